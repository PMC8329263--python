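"""End-to-end orchestration of the coordinated-evolution analysis.

A :class:`RunConfig` names either a synthetic scenario or input files, plus
thresholds and an output directory.  :func:`run_full_analysis` executes the
stages in order — traits, sequences, expression, divergence, hybrid —
writing per-stage TSV outputs with provenance headers (config hash, seed,
package version) and a machine-readable ``summary.json`` that identifies,
per feature class, the node with the largest relative change and the
ANOVA/Tukey/BH significance of per-node differences.

Stages communicate through their files, so a completed stage (matching
config hash) is not recomputed on re-run; outputs of failed stages are
retained for inspection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from c4evo import __version__
from c4evo.divergence import (
    anova_tukey_bh,
    change_rate,
    correlation_matrix,
    divergence_table,
    dn_counting,
    fit_divergence_regression,
)
from c4evo.expression import (
    ExpressionMatrix,
    filter_expressed,
    quantile_normalize,
    rank_conserved_scaling,
)
from c4evo.hybrid import binomial_hybrid_test, call_mixed_sites, mixing_background
from c4evo.sequences import (
    assign_change_node,
    call_c3c4_changes,
    per_node_change_counts,
    protein_relative_difference,
    reconstruct_marginal_sequences,
    stage_summary,
)
from c4evo.simulate import (
    SyntheticScenario,
    proteins_to_cds,
    scenario_tree,
    simulate_allele_counts,
    simulate_bm_traits,
    simulate_expression,
    simulate_protein_alignment,
)
from c4evo.traits import NodeChangeProfile, bm_ancestral_batch, relative_change_continuous

log = logging.getLogger(__name__)

STAGE_ORDER = ("traits", "sequences", "expression", "divergence", "hybrid")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Pipeline settings: inputs, thresholds, output directory and seed."""

    outdir: str = "c4evo_out"
    seed: int = 0
    scenario: SyntheticScenario | None = None
    stages: tuple[str, ...] = STAGE_ORDER
    reference_species: str = "F_cronquistii"
    fpkm_threshold: float = 1.0
    n_ref_genes: int | None = None  # default: scenario.n_ref_genes
    rank_window: tuple[float, float] = (0.20, 0.80)
    min_cov: int = 10
    min_minor_frac: float = 0.2
    min_minor_count: int = 3
    alpha: float = 0.05
    hybrid_alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.scenario is None:
            self.scenario = SyntheticScenario(seed=self.seed)
        self.stages = tuple(self.stages)
        self.rank_window = tuple(self.rank_window)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and isinstance(raw["scenario"], dict):
            raw["scenario"] = SyntheticScenario(**raw["scenario"])
        return cls(**raw)


def _provenance(cfg: RunConfig, stage: str) -> str:
    return (
        f"# c4evo {__version__} stage={stage} seed={cfg.seed} "
        f"config_hash={cfg.config_hash()}\n"
    )


def _write_tsv(cfg: RunConfig, stage: str, name: str, df: pd.DataFrame) -> Path:
    path = Path(cfg.outdir) / name
    with open(path, "w") as fh:
        fh.write(_provenance(cfg, stage))
        df.to_csv(fh, sep="\t")
    return path


def _fragment_path(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.outdir) / f"{stage}_summary.json"


def _stage_done(cfg: RunConfig, stage: str) -> dict | None:
    path = _fragment_path(cfg, stage)
    if path.exists():
        frag = json.loads(path.read_text())
        if frag.get("config_hash") == cfg.config_hash():
            return frag
    return None


def _save_fragment(cfg: RunConfig, stage: str, frag: dict) -> None:
    frag = {"config_hash": cfg.config_hash(), **frag}
    _fragment_path(cfg, stage).write_text(json.dumps(frag, indent=2, sort_keys=True))


def _positive_changes(node_values: pd.DataFrame, overrides) -> dict[str, list[float]]:
    """Per-node relative changes across columns; columns with non-positive
    node values are dropped for the affected profile."""
    groups: dict[str, list[float]] = {}
    for col in node_values.columns:
        vals = node_values[col]
        if (vals <= 0).any():
            continue
        profile = relative_change_continuous(vals.to_dict(), overrides, str(col))
        for node, change in profile.changes.items():
            groups.setdefault(node, []).append(change)
    return groups


def _profile_from_groups(groups: dict[str, list[float]], feature_class: str) -> NodeChangeProfile:
    prof = NodeChangeProfile(feature_class=feature_class)
    for node, vals in groups.items():
        prof.changes[node] = float(np.mean(np.abs(vals)))
    return prof


def _anova_fragment(groups: dict[str, list[float]], alpha: float) -> dict:
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        return {"omnibus_p": None, "significant_pairs": []}
    res = anova_tukey_bh({k: np.abs(v) for k, v in usable.items()})
    sig = res.pairwise[res.pairwise["p_adjusted"] < alpha]
    return {
        "omnibus_p": res.p_omnibus,
        "significant_pairs": [
            f"{r.group1} vs {r.group2} ({r.stars})" for r in sig.itertuples()
        ],
    }


# -- stages ------------------------------------------------------------------------


def stage_traits(cfg: RunConfig, tree, overrides) -> dict:
    tips, true_nodes = simulate_bm_traits(cfg.scenario, tree)
    node_est = bm_ancestral_batch(tree, tips)
    groups = _positive_changes(node_est, overrides)
    profile = _profile_from_groups(groups, "morphology")
    _write_tsv(cfg, "traits", "trait_tips.tsv", tips)
    _write_tsv(cfg, "traits", "trait_node_estimates.tsv", node_est)
    _write_tsv(cfg, "traits", "trait_true_node_values.tsv", true_nodes)
    _write_tsv(
        cfg, "traits", "trait_relative_change.tsv", profile.as_series().to_frame()
    )
    pd.DataFrame(
        [(n, v) for n, vals in groups.items() for v in vals],
        columns=["node", "relative_change"],
    ).to_csv(Path(cfg.outdir) / "trait_change_replicates.tsv", sep="\t", index=False)
    return {
        "n_traits": int(tips.shape[1]),
        "argmax_change_node": profile.argmax_abs(),
        "anova": _anova_fragment(groups, cfg.alpha),
    }


def stage_sequences(cfg: RunConfig, tree, overrides) -> dict:
    alignments, _truth = simulate_protein_alignment(cfg.scenario, tree)
    c3 = [t.label for t in tree.tips() if t.tip_type == "C3"]
    c4 = [t.label for t in tree.tips() if t.tip_type == "C4"]
    rows = []
    anc_sets = []
    for aln in alignments:
        events = call_c3c4_changes(aln, c3, c4)
        anc = reconstruct_marginal_sequences(tree, aln)
        anc_sets.append(anc)
        for ev in events:
            assign_change_node(ev, anc, overrides, tree, aln)
        _, stages = per_node_change_counts(events)
        rows.append(
            {
                "orthogroup": aln.orthogroup_id,
                "total_changes": len(events),
                **stages,
            }
        )
    table = pd.DataFrame(rows).set_index("orthogroup")
    profile = protein_relative_difference(anc_sets, overrides)
    groups: dict[str, list[float]] = {}
    for anc in anc_sets:
        prof = protein_relative_difference(anc, overrides)
        for node, val in prof.changes.items():
            groups.setdefault(node, []).append(val)
    _write_tsv(cfg, "sequences", "sequence_stage_counts.tsv", table)
    _write_tsv(
        cfg, "sequences", "protein_relative_difference.tsv", profile.as_series().to_frame()
    )
    total = int(table["total_changes"].sum())
    at_n7 = int(table["at N7"].sum()) if "at N7" in table else 0
    return {
        "n_genes": len(alignments),
        "total_changes": total,
        "changes_at_N7": at_n7,
        "argmax_change_node": profile.argmax_abs(),
        "anova": _anova_fragment(groups, cfg.alpha),
    }


def stage_expression(cfg: RunConfig, tree, overrides) -> dict:
    values, metadata, truth = simulate_expression(cfg.scenario, tree)
    matrix = ExpressionMatrix(values, metadata)
    filtered = filter_expressed(matrix, cfg.fpkm_threshold)
    n_ref = cfg.n_ref_genes or cfg.scenario.n_ref_genes
    scaled = rank_conserved_scaling(filtered, n_ref=n_ref, window=cfg.rank_window)
    species_mean = (
        scaled.values.T.groupby(scaled.metadata.loc[scaled.values.columns, "species"].values)
        .mean()
        .T
    )
    node_est = bm_ancestral_batch(tree, species_mean.T)
    groups = _positive_changes(node_est, overrides)
    profile = _profile_from_groups(groups, "expression")
    qnorm = quantile_normalize(species_mean)
    _write_tsv(cfg, "expression", "expression_scaled.tsv", scaled.values)
    _write_tsv(cfg, "expression", "expression_species_mean.tsv", species_mean)
    _write_tsv(cfg, "expression", "expression_qnorm.tsv", qnorm)
    _write_tsv(
        cfg, "expression", "expression_relative_change.tsv", profile.as_series().to_frame()
    )
    (Path(cfg.outdir) / "de_genes_truth.txt").write_text("\n".join(truth["de_genes"]) + "\n")
    return {
        "n_genes_total": int(values.shape[0]),
        "n_genes_expressed": int(filtered.values.shape[0]),
        "n_de_truth": len(truth["de_genes"]),
        "argmax_change_node": profile.argmax_abs(),
        "anova": _anova_fragment(groups, cfg.alpha),
    }


def stage_divergence(cfg: RunConfig, tree, overrides) -> dict:
    ref = cfg.reference_species
    qnorm = pd.read_csv(
        Path(cfg.outdir) / "expression_qnorm.tsv", sep="\t", comment="#", index_col=0
    )
    tips = pd.read_csv(
        Path(cfg.outdir) / "trait_tips.tsv", sep="\t", comment="#", index_col=0
    )
    morph_qnorm = quantile_normalize(tips.T - tips.min().min() + 1.0)
    alignments, _ = simulate_protein_alignment(cfg.scenario, tree)
    cds = proteins_to_cds(alignments, cfg.scenario.rng("sequences"))
    species = tree.tip_labels()
    super_cds = {sp: "".join(cds[og][sp] for og in sorted(cds)) for sp in species}
    dn = {sp: dn_counting(super_cds[ref], super_cds[sp]) for sp in species}
    table = divergence_table(ref, protein_dn=dn, expression=qnorm, morphology=morph_qnorm)
    regressions = {}
    cols = list(table.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = table[[a, b]].dropna()
            slope, intercept, r2, p = fit_divergence_regression(sub[a], sub[b])
            regressions[f"{a}~{b}"] = {"slope": slope, "r2": r2, "p": p}
    profiles = []
    for name, fname in [
        ("morphology", "trait_relative_change.tsv"),
        ("expression", "expression_relative_change.tsv"),
        ("protein", "protein_relative_difference.tsv"),
    ]:
        series = pd.read_csv(
            Path(cfg.outdir) / fname, sep="\t", comment="#", index_col=0
        ).iloc[:, 0]
        prof = NodeChangeProfile(feature_class=name, changes=series.to_dict())
        profiles.append(prof)
    corr = correlation_matrix(profiles)
    branch_lengths = {
        n.label: n.length for n in tree.internal_nodes() if n.parent is not None
    }
    rates = pd.DataFrame(
        {p.feature_class: change_rate(p, branch_lengths) for p in profiles}
    )
    _write_tsv(cfg, "divergence", "divergence_table.tsv", table)
    _write_tsv(cfg, "divergence", "change_profile_correlations.tsv", corr)
    _write_tsv(cfg, "divergence", "change_rates.tsv", rates)
    return {
        "reference": ref,
        "regressions": regressions,
        "max_change_rate_node": {c: rates[c].idxmax() for c in rates.columns},
    }


def stage_hybrid(cfg: RunConfig, tree, overrides) -> dict:
    tables, flags = simulate_allele_counts(cfg.scenario, tree)
    kw = dict(
        min_cov=cfg.min_cov,
        min_minor_frac=cfg.min_minor_frac,
        min_minor_count=cfg.min_minor_count,
    )
    results = {name: call_mixed_sites(t, **kw) for name, t in tables.items()}
    pure = [tables[name] for name, hyb in flags.items() if not hyb]
    background = mixing_background(pure, **kw)
    rows = []
    verdicts = {}
    for name, res in results.items():
        res = binomial_hybrid_test(res, background, alpha=cfg.hybrid_alpha)
        verdicts[name] = res.verdict
        rows.append(
            {
                "sample": name,
                "n_evaluable": res.n_evaluable,
                "n_mixed": res.n_mixed,
                "ratio": res.ratio,
                "p_higher": res.p_higher,
                "p_lower": res.p_lower,
                "verdict": res.verdict,
                "is_hybrid_truth": flags[name],
            }
        )
    _write_tsv(cfg, "hybrid", "hybrid_verdicts.tsv", pd.DataFrame(rows).set_index("sample"))
    pd.Series(background, name="background_ratio").to_csv(
        Path(cfg.outdir) / "hybrid_background_ratios.tsv", sep="\t", index=False
    )
    n_correct = sum(
        (verdicts[name] == ("hybrid-like" if hyb else "non-hybrid"))
        for name, hyb in flags.items()
    )
    return {
        "n_samples": len(tables),
        "n_background_pairs": int(len(background)),
        "verdicts": verdicts,
        "n_correct_verdicts": int(n_correct),
    }


_STAGE_FN = {
    "traits": stage_traits,
    "sequences": stage_sequences,
    "expression": stage_expression,
    "divergence": stage_divergence,
    "hybrid": stage_hybrid,
}


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the configured stages and write ``summary.json``.

    Stages with an up-to-date summary fragment (same config hash) are
    skipped.  A stage failure raises :class:`StageError` naming the stage;
    outputs of completed stages are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = scenario_tree(cfg.scenario)
    overrides = tree.preceding_overrides()
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        frag = _stage_done(cfg, stage)
        if frag is None:
            log.info("running stage %s", stage)
            try:
                frag = _STAGE_FN[stage](cfg, tree, overrides)
            except Exception as exc:
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
            _save_fragment(cfg, stage, frag)
            frag = _stage_done(cfg, stage)
        else:
            log.info("stage %s up to date; skipping", stage)
        summary["stages"][stage] = {k: v for k, v in frag.items() if k != "config_hash"}
    feature_names = {"traits": "morphology", "sequences": "protein", "expression": "expression"}
    summary["argmax_change_node"] = {
        feature_names[s]: summary["stages"][s]["argmax_change_node"]
        for s in feature_names
        if s in summary["stages"] and "argmax_change_node" in summary["stages"][s]
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
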