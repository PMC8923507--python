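"""Liquid–liquid phase-separation (LLPS) propensity stratification.

Proteins carry a predicted phase-separation probability (pLLPS) in [0, 1];
those above the droplet-formation cutoff (default 0.64) are classified as
high-propensity.  The cross-tabulation relates LLPS class to disorder
class, TF status, stress-pathway membership and interaction count.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .annotations import ProteinRecord
from .disorder_profiles import DisorderSummary
from .network import PPINetwork, partner_proportions

__all__ = ["LLPS_CUTOFF", "LLPSRecord", "classify_llps", "llps_disorder_crosstab", "CrosstabResult"]

#: Droplet-formation probability cutoff; values strictly above are "high".
LLPS_CUTOFF = 0.64


@dataclass(frozen=True)
class LLPSRecord:
    protein_id: str
    pllps: float
    llps_class: str


def classify_llps(pllps: float, cutoff: float = LLPS_CUTOFF, strict: bool = True) -> str:
    """Classify a pLLPS value as ``high`` or ``low``.

    The default is strict (``high`` iff pllps > cutoff, so the cutoff value
    itself is ``low``); set ``strict=False`` for an inclusive >= rule.
    """
    if not (0.0 <= pllps <= 1.0):
        raise ValueError(f"pllps out of range: {pllps}")
    above = pllps > cutoff if strict else pllps >= cutoff
    return "high" if above else "low"


@dataclass
class CrosstabResult:
    """LLPS cross-tabulation outputs.

    ``counts``: llps_class x disorder_class x TF x stress contingency counts;
    ``fraction_high``: share of high-pLLPS proteins per disorder/TF/stress
    stratum; ``partner_props``: partner-proportion matrix by llps_class
    (None when no network is supplied); ``table``: the joined per-protein
    table the tallies are computed from.
    """

    counts: pd.DataFrame
    fraction_high: pd.DataFrame
    partner_props: pd.DataFrame | None
    table: pd.DataFrame


def llps_disorder_crosstab(
    records: Sequence[ProteinRecord],
    summaries: Sequence[DisorderSummary],
    degrees: Mapping[str, int] | None = None,
    network: PPINetwork | None = None,
    cutoff: float = LLPS_CUTOFF,
    strict: bool = True,
    stress_pathways: Sequence[str] | None = None,
) -> CrosstabResult:
    """Cross-tabulate LLPS class against disorder class, TF flag and stress membership.

    Records lacking a pLLPS value or a disorder summary cause an error
    naming the ids (inputs must be joinable).  When ``network`` is given,
    the partner-proportion matrix by LLPS class is computed as well.
    The boundary convention (strict > by default) is stated in the output
    table attributes for downstream writers.
    """
    by_id = {s.protein_id: s for s in summaries}
    missing_summary = sorted(r.protein_id for r in records if r.protein_id not in by_id)
    missing_pllps = sorted(r.protein_id for r in records if r.pllps is None)
    if missing_summary or missing_pllps:
        raise ValueError(
            f"unjoinable ids — no disorder summary: {missing_summary[:5]}, "
            f"no pLLPS: {missing_pllps[:5]}"
        )
    stress = set(stress_pathways) if stress_pathways is not None else None

    def in_stress(r: ProteinRecord) -> bool:
        paths = r.pathways if stress is None else (r.pathways & stress)
        return bool(paths)

    table = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "pllps": [r.pllps for r in records],
            "llps_class": [classify_llps(r.pllps, cutoff, strict) for r in records],
            "disorder_class": [by_id[r.protein_id].disorder_class.name for r in records],
            "is_tf": [r.is_tf for r in records],
            "in_stress": [in_stress(r) for r in records],
        }
    )
    if degrees is not None:
        table["degree"] = [degrees.get(r.protein_id, 0) for r in records]
    table.attrs["cutoff"] = cutoff
    table.attrs["boundary"] = "high iff pllps > cutoff" if strict else "high iff pllps >= cutoff"

    counts = (
        table.groupby(["llps_class", "disorder_class", "is_tf", "in_stress"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    frac = (
        table.assign(high=table["llps_class"] == "high")
        .groupby(["disorder_class", "is_tf", "in_stress"], observed=False)["high"]
        .agg(fraction_high="mean", n="size")
        .reset_index()
    )
    partner = None
    if network is not None:
        llps_of = dict(zip(table["protein_id"], table["llps_class"]))
        partner, _ = partner_proportions(network, llps_of, default_category="unscored")
    return CrosstabResult(counts=counts, fraction_high=frac, partner_props=partner, table=table)


def write_crosstab(result: CrosstabResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pLLPS cutoff {result.table.attrs['cutoff']}; {result.table.attrs['boundary']}\n")
        fh.write("# [counts]\n")
        result.counts.to_csv(fh, sep="\t", index=False)
        fh.write("# [fraction_high]\n")
        result.fraction_high.to_csv(fh, sep="\t", index=False)
        if result.partner_props is not None:
            fh.write("# [partner_proportions by llps_class]\n")
            result.partner_props.to_csv(fh, sep="\t")
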