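"""End-to-end orchestration: from inputs (real files or a synthetic spec)
to the summary artifacts of the analysis.

A run produces, in the output directory: ``proteome_summary.tsv`` (per
protein: mean score, D_ratio, IDR count, class), ``idr_counts_by_group.tsv``
(Fig-2-style IDR tallies per disorder band with pairwise rank-sum
contrasts), ``dratio_histogram.tsv``, ``pathway_matrix.tsv``
(Table-2-style pathway x category counts), ``enrichment.tsv``,
``degree_comparisons.tsv``, ``partner_proportions.tsv``,
``llps_crosstab.tsv``, ``run.log`` (one line per stage with input/output
counts) and ``metrics.json`` (machine-readable headline numbers,
bit-reproducible for a fixed config and seed).
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from . import disorder_profiles as dp
from . import enrichment as enr
from . import llps as llps_mod
from . import network as net
from .synthetic_data import SyntheticDataset, SyntheticSpec, generate_proteome, write_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "pathway_matrix", "dratio_histogram"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs, thresholds and constants of one run in one place.

    Exactly one of ``synthetic`` (a SyntheticSpec) or the real-input paths
    (``fasta``/``scores``/``annotations``/``edges``/``pllps``) must be
    active.
    """

    output_dir: str = "idphub_out"
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    fasta: str | None = None
    scores: str | None = None
    annotations: str | None = None
    edges: str | None = None
    pllps: str | None = None
    reference_predictor: str = dp.CONSENSUS_ID
    residue_threshold: float = dp.RESIDUE_THRESHOLD
    min_window: int = dp.MIN_IDR_WINDOW
    consensus: dp.ConsensusParams = field(default_factory=dp.ConsensusParams)
    llps_cutoff: float = llps_mod.LLPS_CUTOFF
    llps_strict: bool = True
    alpha: float = 0.05
    correction: str = "fdr_bh"
    significance_on: str = "adjusted"
    enrichment_universe: str = "annotated"  # or "proteome"
    write_synthetic_inputs: bool = False

    def __post_init__(self) -> None:
        real = [self.fasta, self.scores, self.annotations]
        if self.synthetic is not None and any(p is not None for p in real):
            raise ValueError("config must use either a synthetic spec or real inputs, not both")
        if self.synthetic is None and self.scores is None:
            raise ValueError("config needs either a synthetic spec or real input paths")
        if not (0.0 <= self.residue_threshold <= 1.0):
            raise ValueError("residue_threshold must be in [0, 1]")
        if not (0.0 <= self.llps_cutoff <= 1.0):
            raise ValueError("llps_cutoff must be in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_window < 1:
            raise ValueError("min_window must be >= 1")
        if self.enrichment_universe not in {"annotated", "proteome"}:
            raise ValueError("enrichment_universe must be 'annotated' or 'proteome'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("length_range", "pathway_names", "pathway_sizes", "planted_enrichment_odds"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "dratio_mixture" in syn:
                syn["dratio_mixture"] = tuple(
                    (float(w), (float(a), float(b))) for w, (a, b) in syn["dratio_mixture"]
                )
            raw["synthetic"] = SyntheticSpec(**syn)
        if "consensus" in raw and raw["consensus"] is not None:
            raw["consensus"] = dp.ConsensusParams(**raw["consensus"])
        return cls(**raw)


def dratio_histogram(summaries: Sequence[dp.DisorderSummary], bin_width: float = 0.1) -> pd.DataFrame:
    """Left-closed D_ratio bins over [0, 1]; the last bin includes 1.0.

    Returns a DataFrame with bin edges, counts and fractions (summing to 1).
    """
    if not summaries:
        raise ValueError("dratio_histogram requires at least one summary")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    vals = np.array([s.d_ratio for s in summaries])
    # np.histogram bins are left-closed with a right-inclusive final bin,
    # exactly the dialect wanted here
    counts, _ = np.histogram(vals, bins=edges)
    frac = counts / counts.sum()
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts, "fraction": frac}
    )


_CATEGORIES = ["non_idp_non_tf", "non_idtf", "idp_non_tf", "idtf"]


def _category(is_idp: bool, is_tf: bool) -> str:
    if is_tf:
        return "idtf" if is_idp else "non_idtf"
    return "idp_non_tf" if is_idp else "non_idp_non_tf"


def pathway_matrix(
    records: Sequence[ann.ProteinRecord], summaries: Sequence[dp.DisorderSummary]
) -> pd.DataFrame:
    """Pathway x protein-category counts (Table-2 style).

    Each protein falls into exactly one of four mutually exclusive
    categories — non-IDP non-TF, TF but not IDP, IDP but not TF, IDTF —
    where IDP means disorder class HD.  Proteins belonging to several
    pathways are counted in each pathway row; ``total`` is the row sum of
    the four cells.
    """
    cls = {s.protein_id: s.is_idp for s in summaries}
    pathways = sorted({p for r in records for p in r.pathways})
    mat = pd.DataFrame(0, index=pathways, columns=_CATEGORIES, dtype=int)
    for r in records:
        if not r.pathways:
            continue
        cat = _category(cls.get(r.protein_id, False), r.is_tf)
        for p in r.pathways:
            mat.loc[p, cat] += 1
    mat["total"] = mat[_CATEGORIES].sum(axis=1)
    mat.index.name = "pathway"
    return mat


def _class_letter(cls: dp.DisorderClass) -> str:
    return {"LD": "L", "MD": "M", "HD": "H"}.get(cls.name, cls.name)


def _summaries_for(
    tracks_by_protein: dict[str, list[dp.ResidueScoreTrack]], config: RunConfig
) -> list[dp.DisorderSummary]:
    return [
        dp.summarize_protein(
            tracks,
            reference_predictor=config.reference_predictor,
            min_window=config.min_window,
            threshold=config.residue_threshold,
            consensus_params=config.consensus,
        )
        for tracks in tracks_by_protein.values()
    ]


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    summaries: list[dp.DisorderSummary]
    records: list[ann.ProteinRecord]
    network: net.PPINetwork
    metrics: dict
    output_dir: Path
    dataset: SyntheticDataset | None = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage; any failure aborts with the stage name and cause."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    dataset: SyntheticDataset | None = None
    stage = "load"
    try:
        if config.synthetic is not None:
            spec = replace(config.synthetic, seed=config.seed)
            dataset = generate_proteome(spec)
            if config.write_synthetic_inputs:
                write_dataset(dataset, out / "inputs")
            records = dataset.proteins
            tracks = dataset.tracks
            edges = dataset.edges
            term_map = dataset.term_map
            log(stage, f"synthetic proteome: {len(records)} proteins, seed {config.seed}")
        else:
            proteome = ann.read_fasta(config.fasta) if config.fasta else None
            tracks = dp.read_score_table(config.scores)
            records, unmatched = (
                ann.read_annotation_table(config.annotations, proteome)
                if config.annotations
                else ([], [])
            )
            if config.annotations and unmatched:
                ann.write_unmatched_report(unmatched, out / "unmatched_ids.tsv")
            pllps_map = ann.read_pllps_table(config.pllps) if config.pllps else {}
            for r in records:
                if r.protein_id in pllps_map:
                    r.pllps = pllps_map[r.protein_id]
            edges_net = net.read_edges(config.edges, mv_only=True) if config.edges else net.PPINetwork()
            edges = edges_net.edges
            term_map = {}
            for r in records:
                for p in r.pathways:
                    term_map.setdefault(p, set()).add(r.protein_id)
            log(stage, f"real inputs: {len(records)} annotated proteins, "
                       f"{len({t.protein_id for t in tracks})} scored proteins")
    except Exception as exc:  # noqa: BLE001 - stage accounting
        raise PipelineError(stage, exc) from exc

    stage = "profiles"
    try:
        tracks_by_protein = dp.group_tracks_by_protein(tracks)
        summaries = _summaries_for(tracks_by_protein, config)
        dp.write_summary_table(summaries, out / "proteome_summary.tsv")
        dp.write_idr_bed(summaries, out / "idr_intervals.bed.tsv")
        log(stage, f"{len(summaries)} proteins summarised "
                   f"(reference: {config.reference_predictor})")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    by_id = {s.protein_id: s for s in summaries}
    n_prot = len(summaries)
    idps = [s.protein_id for s in summaries if s.is_idp]
    tf_ids = [r.protein_id for r in records if r.is_tf]
    tf_summ = [by_id[t] for t in tf_ids if t in by_id]

    stage = "histogram"
    try:
        if summaries:
            hist = dratio_histogram(summaries)
            hist.to_csv(out / "dratio_histogram.tsv", sep="\t", index=False)
        log(stage, f"{len(idps)} IDPs / {n_prot} proteins")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "idr_groups"
    try:
        group_rows = []
        idr_by_class: dict[str, list[int]] = {}
        for subset, name in ((summaries, "all"), (tf_summ, "tf")):
            for cls in (dp.DisorderClass.LD, dp.DisorderClass.MD, dp.DisorderClass.HD):
                counts = [s.idr_count for s in subset if s.disorder_class is cls]
                group_rows.append(
                    (name, cls.name, len(counts), float(np.mean(counts)) if counts else np.nan)
                )
                if name == "all":
                    idr_by_class[_class_letter(cls)] = counts
        pd.DataFrame(
            group_rows, columns=["subset", "class", "n_proteins", "mean_idr_count"]
        ).to_csv(out / "idr_counts_by_group.tsv", sep="\t", index=False)
        log(stage, "IDR tallies per disorder band written")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "pathway_matrix"
    try:
        pmat = pathway_matrix(records, summaries)
        pmat.to_csv(out / "pathway_matrix.tsv", sep="\t")
        log(stage, f"{len(pmat)} pathways tallied")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "enrichment"
    try:
        if term_map and idps:
            annotated = sorted({pid for members in term_map.values() for pid in members})
            universe = (
                annotated
                if config.enrichment_universe == "annotated"
                else [s.protein_id for s in summaries]
            )
            fg = sorted(set(idps) & set(universe))
            res = enr.enrich(
                fg, universe, term_map, alpha=config.alpha,
                correction=config.correction, significance_on=config.significance_on,
            )
            enr.write_enrichment_table(res, out / "enrichment.tsv")
            enrich_table = res.table
            log(stage, f"{len(enrich_table)} terms tested, "
                       f"{int(enrich_table['significant'].sum())} significant")
        else:
            enrich_table = pd.DataFrame()
            log(stage, "skipped (no terms or no IDPs)")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "network"
    try:
        network = net.PPINetwork(edges)
        degrees = {
            pid: (net.node_degree(network, pid) if pid in network else 0) for pid in by_id
        }
        comparisons: dict[str, list[net.GroupComparison]] = {}
        for subset, name in ((summaries, "all"), (tf_summ, "tf")):
            values = {
                _class_letter(cls): [
                    degrees[s.protein_id]
                    for s in subset
                    if s.disorder_class is cls
                ]
                for cls in (dp.DisorderClass.LD, dp.DisorderClass.MD, dp.DisorderClass.HD)
            }
            nonempty = {g: v for g, v in values.items() if v}
            if len(nonempty) >= 2:
                comparisons[name] = net.pairwise_group_comparison(nonempty, alpha=config.alpha)
        all_comp = [
            c
            for name, comps in comparisons.items()
            for c in comps
        ]
        with open(out / "degree_comparisons.tsv", "w") as fh:
            fh.write("# degree contrasts by disorder band (L/M/H), all proteins and TFs\n")
            pd.DataFrame(
                [
                    (name, c.group_a, c.group_b, c.statistic, c.p_raw, c.p_bonferroni, c.significant)
                    for name, comps in comparisons.items()
                    for c in comps
                ],
                columns=["subset", "group_a", "group_b", "statistic", "p_raw",
                         "p_bonferroni", "significant"],
            ).to_csv(fh, sep="\t", index=False)
        tf_set = set(tf_ids)
        category_of = {
            s.protein_id: f"{'tf' if s.protein_id in tf_set else 'nontf'}_{_class_letter(s.disorder_class)}"
            for s in summaries
        }
        props, prop_counts = net.partner_proportions(network, category_of)
        props.to_csv(out / "partner_proportions.tsv", sep="\t")
        log(stage, f"{network.n_nodes} nodes, {network.n_edges} edges")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "llps"
    try:
        scored = [r for r in records if r.pllps is not None and r.protein_id in by_id]
        if scored:
            cross = llps_mod.llps_disorder_crosstab(
                scored,
                [by_id[r.protein_id] for r in scored],
                degrees=degrees,
                network=network,
                cutoff=config.llps_cutoff,
                strict=config.llps_strict,
            )
            llps_mod.write_crosstab(cross, out / "llps_crosstab.tsv")
            frac_high_all = float((cross.table["llps_class"] == "high").mean())
            tf_mask = cross.table["is_tf"]
            frac_high_tf = float(
                (cross.table.loc[tf_mask, "llps_class"] == "high").mean()
            ) if tf_mask.any() else float("nan")
            log(stage, f"{len(scored)} proteins cross-tabulated")
        else:
            frac_high_all = frac_high_tf = float("nan")
            log(stage, "skipped (no pLLPS values)")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "metrics"
    try:
        tf_with_idr = [s for s in tf_summ if s.idr_count >= 1]
        all_with_idr = [s for s in summaries if s.idr_count >= 1]
        class_counts = {
            cls.name: sum(1 for s in summaries if s.disorder_class is cls)
            for cls in dp.DisorderClass
        }
        metrics = {
            "seed": config.seed,
            "n_proteins": n_prot,
            "idp_count": len(idps),
            "idp_fraction": (len(idps) / n_prot) if n_prot else float("nan"),
            "class_counts": class_counts,
            "tf_count": len(tf_ids),
            "idtf_count": sum(1 for s in tf_summ if s.is_idp),
            "tf_with_idr_fraction": (len(tf_with_idr) / len(tf_summ)) if tf_summ else float("nan"),
            "proteome_with_idr_fraction": (len(all_with_idr) / n_prot) if n_prot else float("nan"),
            "network": {
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "tf_degree_means": {
                    g: float(np.mean([degrees[s.protein_id] for s in tf_summ
                                      if _class_letter(s.disorder_class) == g] or [np.nan]))
                    for g in ("L", "M", "H")
                },
                "comparisons": {
                    name: [
                        {"pair": f"{c.group_a}-{c.group_b}", "p_raw": c.p_raw,
                         "p_bonferroni": c.p_bonferroni, "significant": bool(c.significant)}
                        for c in comps
                    ]
                    for name, comps in comparisons.items()
                },
            },
            "enrichment": {
                "n_terms": int(len(enrich_table)),
                "n_significant": int(enrich_table["significant"].sum()) if len(enrich_table) else 0,
                "top_term": (str(enrich_table.iloc[0]["term_id"]) if len(enrich_table) else None),
                "top_q": (float(enrich_table.iloc[0]["q_adj"]) if len(enrich_table) else None),
            },
            "llps": {
                "fraction_high": frac_high_all,
                "fraction_high_tf": frac_high_tf,
            },
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, sort_keys=True, allow_nan=True)
        log(stage, "metrics written")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return RunResult(
        config=config,
        summaries=summaries,
        records=list(records),
        network=network,
        metrics=metrics,
        output_dir=out,
        dataset=dataset,
    )
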