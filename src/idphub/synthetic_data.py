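"""Synthetic proteome generator with known ground truth.

Every stage of the analysis (disorder calling, consensus, class
stratification, enrichment, degree analysis, LLPS stratification) is
testable offline against datasets generated here: protein sequences with
planted disordered blocks, several noisy per-residue score tracks with a
controlled probability of agreeing with the planted truth, TF flags,
stress-pathway memberships with planted over-representation of the true
IDPs, degree-structured interaction edges with a planted disorder effect
on TF connectivity, and pLLPS values linearly coupled to the true disorder
ratio.

Design choices
--------------
* Disordered blocks are at least ``idr_block_min`` residues (default 30,
  the IDR window definition) and are separated by at least
  ``min_block_gap`` ordered residues (default 7, wider than the consensus
  smoothing element) so every planted block is recoverable as one maximal
  run.
* Score tracks jitter a piecewise-constant truth profile (0.8 inside
  blocks, 0.2 outside) with truncated-Gaussian noise confined to the
  correct side of the 0.5 threshold; disagreeing residues (probability
  ``1 - agreement``) are emitted on the wrong side, so the marginal
  per-residue concordance with truth equals the agreement parameter.
* Degrees are Poisson with group-specific means realised by a
  configuration-style stub pairing; the planted effect raises the mean
  degree of highly disordered TFs.
* All randomness flows from the single integer seed through one
  ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .annotations import STRESS_PATHWAYS, ProteinRecord
from .disorder_profiles import DisorderClass, IDRInterval, ResidueScoreTrack, classify_disorder

__all__ = ["SyntheticSpec", "SyntheticDataset", "SpecValidationError",
           "generate_proteome", "generate_score_tracks", "generate_ppi",
           "write_dataset"]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_COMPARTMENTS = ("nucleus", "cytosol", "mitochondrion", "ER", "vacuole", "membrane")
_SOURCES = ("gfp", "curated")


class SpecValidationError(ValueError):
    """Raised when a SyntheticSpec field is out of range; names the field."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome.

    Defaults emulate the analysed yeast proteome at desk scale: 2,000
    proteins (scaled from 6,721), ~2.5% TFs, a disorder-ratio mixture
    placing 7.7% of proteins in the IDP band and ~79% below 0.3, three
    predictors at 95% per-residue concordance with truth, the five stress
    pathways with IDP over-representation planted at odds 5 in four of
    them, a mean interaction degree of 8 with a +5 effect for disordered
    TFs, and pLLPS = clip(0.9 * D_ratio + 0.2 + noise).
    """

    n_proteins: int = 2000
    length_range: tuple[int, int] = (200, 800)
    frac_tf: float = 0.025
    dratio_mixture: tuple[tuple[float, tuple[float, float]], ...] = (
        (0.400, (0.00, 0.10)),
        (0.393, (0.12, 0.28)),
        (0.130, (0.32, 0.48)),
        (0.077, (0.52, 0.88)),
    )
    idr_block_mean: int = 60
    idr_block_min: int = 30
    min_block_gap: int = 7
    n_predictors: int = 3
    predictor_noise_sd: float = 0.1
    predictor_agreement: float = 0.95
    pathway_names: tuple[str, ...] = STRESS_PATHWAYS
    #: explicit pathway member counts; None scales the reference stress-map
    #: sizes (101/110/182/138/150 proteins out of a 6,721-protein proteome)
    #: proportionally to n_proteins
    pathway_sizes: tuple[int, ...] | None = None
    planted_enrichment_odds: tuple[float, ...] = (5.0, 1.0, 5.0, 5.0, 5.0)
    degree_baseline: float = 8.0
    degree_disorder_effect: float = 5.0
    pllps_slope: float = 0.9
    pllps_intercept: float = 0.2
    pllps_noise_sd: float = 0.05
    seed: int = 0

    #: reference pathway sizes relative to a 6,721-protein proteome
    _REFERENCE_PATHWAY_SIZES = (101, 110, 182, 138, 150)
    _REFERENCE_PROTEOME = 6721

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)

    def resolved_pathway_sizes(self) -> tuple[int, ...]:
        if self.pathway_sizes is not None:
            return self.pathway_sizes
        ref = (self._REFERENCE_PATHWAY_SIZES * ((self.n_pathways // 5) + 1))[: self.n_pathways]
        return tuple(
            min(self.n_proteins, max(1, round(self.n_proteins * s / self._REFERENCE_PROTEOME)))
            for s in ref
        )

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise SpecValidationError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise SpecValidationError("length_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.frac_tf <= 1.0):
            raise SpecValidationError("frac_tf must be in [0, 1]")
        weights = [w for w, _ in self.dratio_mixture]
        if not self.dratio_mixture or abs(sum(weights) - 1.0) > 1e-9:
            raise SpecValidationError("dratio_mixture weights must sum to 1")
        for w, (a, b) in self.dratio_mixture:
            if w < 0 or not (0.0 <= a <= b <= 1.0):
                raise SpecValidationError("dratio_mixture intervals must lie in [0, 1]")
            # an interval with a positive lower edge must be reachable with
            # blocks of at least idr_block_min residues at the minimum length
            if b > 0 and int(np.floor(b * lo)) < self.idr_block_min and a > 0:
                raise SpecValidationError(
                    "dratio_mixture interval unreachable: "
                    f"[{a}, {b}] needs more than floor({b} * {lo}) disordered "
                    f"residues but blocks are >= idr_block_min={self.idr_block_min}"
                )
        if self.idr_block_min < 1:
            raise SpecValidationError("idr_block_min must be >= 1")
        if self.idr_block_mean < self.idr_block_min:
            raise SpecValidationError("idr_block_mean must be >= idr_block_min")
        if self.min_block_gap < 1:
            raise SpecValidationError("min_block_gap must be >= 1")
        if self.n_predictors < 0:
            raise SpecValidationError("n_predictors must be >= 0")
        if self.predictor_noise_sd < 0 or self.predictor_noise_sd > 1:
            raise SpecValidationError("predictor_noise_sd must be in [0, 1]")
        if not (0.0 <= self.predictor_agreement <= 1.0):
            raise SpecValidationError("predictor_agreement must be in [0, 1]")
        if self.pathway_sizes is not None:
            if len(self.pathway_sizes) != self.n_pathways:
                raise SpecValidationError("pathway_sizes must match pathway_names")
            if any(s < 0 or s > self.n_proteins for s in self.pathway_sizes):
                raise SpecValidationError("pathway_sizes must be in [0, n_proteins]")
        if len(self.planted_enrichment_odds) != self.n_pathways:
            raise SpecValidationError("planted_enrichment_odds must match pathway_names")
        if any(o <= 0 for o in self.planted_enrichment_odds):
            raise SpecValidationError("planted_enrichment_odds must be positive")
        if self.degree_baseline < 0 or self.degree_baseline + self.degree_disorder_effect < 0:
            raise SpecValidationError("degree means must be >= 0")
        if self.pllps_noise_sd < 0:
            raise SpecValidationError("pllps_noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated proteome with its ground truth."""

    spec: SyntheticSpec
    proteins: list[ProteinRecord] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    truth_masks: dict[str, np.ndarray] = field(default_factory=dict)
    tracks: list[ResidueScoreTrack] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    term_map: dict[str, set[str]] = field(default_factory=dict)
    truth_class: dict[str, DisorderClass] = field(default_factory=dict)
    truth_intervals: dict[str, list[IDRInterval]] = field(default_factory=dict)
    truth_dratio: dict[str, float] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]


def _plant_blocks(
    length: int,
    interval: tuple[float, float],
    rng: np.random.Generator,
    block_min: int,
    block_mean: int,
    min_gap: int,
) -> np.ndarray:
    """Boolean truth mask with disordered blocks whose total fits ``interval``."""
    lo, hi = interval
    lo_c = int(np.ceil(lo * length - 1e-9))
    hi_c = int(np.floor(hi * length + 1e-9))
    choices: list[int]
    if lo == 0.0:
        choices = [0] + list(range(block_min, hi_c + 1))
    else:
        choices = list(range(max(lo_c, block_min), hi_c + 1))
    if not choices:
        raise SpecValidationError(
            f"dratio_mixture interval [{lo}, {hi}] infeasible at length {length}"
        )
    n_dis = int(rng.choice(choices))
    mask = np.zeros(length, dtype=bool)
    if n_dis == 0:
        return mask
    k_max = max(1, min(n_dis // block_min, (length - n_dis) // min_gap + 1))
    k = int(np.clip(round(n_dis / block_mean), 1, k_max))
    # block lengths: min length each plus a random composition of the excess
    extra = n_dis - k * block_min
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1)) if k > 1 else np.array([], dtype=int)
    parts = np.diff(np.concatenate(([0], cuts, [extra])))
    block_lengths = parts + block_min
    # gaps: ends may be 0, interior gaps at least min_gap
    slack = length - n_dis - min_gap * (k - 1)
    gcuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate(([0], gcuts, [slack])))
    gaps[1:-1] += min_gap
    pos = 0
    for blen, gap in zip(block_lengths, gaps[:-1]):
        pos += int(gap)
        mask[pos : pos + int(blen)] = True
        pos += int(blen)
    return mask


def generate_score_tracks(
    truth_masks: Mapping[str, np.ndarray],
    n_predictors: int,
    noise_sd: float,
    agreement: float,
    rng: np.random.Generator | int | None = None,
) -> list[ResidueScoreTrack]:
    """Emit noisy per-residue score tracks for every protein and predictor.

    Each residue's score lands on the truth side of the 0.5 threshold with
    probability ``agreement`` and on the wrong side otherwise, so binarised
    concordance with truth is Binomial(L, agreement).  Scores are 0.8/0.2
    (disordered/ordered side) plus truncated-Gaussian jitter of spread
    ``noise_sd`` confined to the side.
    """
    if not (0.0 <= agreement <= 1.0):
        raise SpecValidationError("predictor_agreement must be in [0, 1]")
    if noise_sd < 0:
        raise SpecValidationError("predictor_noise_sd must be >= 0")
    if not truth_masks:
        raise ValueError("truth_masks must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = list(truth_masks)
    lengths = [len(truth_masks[pid]) for pid in ids]
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    truth_all = np.concatenate([np.asarray(truth_masks[pid], dtype=bool) for pid in ids])

    tracks: list[ResidueScoreTrack] = []
    for p in range(n_predictors):
        agree = rng.random(truth_all.size) < agreement
        side = truth_all == agree  # disordered-side call per residue
        scores = np.empty(truth_all.size)
        if noise_sd == 0:
            scores[side] = 0.8
            scores[~side] = 0.2
        else:
            u = rng.random(truth_all.size)
            a_d, b_d = (0.5 - 0.8) / noise_sd, (1.0 - 0.8) / noise_sd
            a_o, b_o = (0.0 - 0.2) / noise_sd, (0.5 - 0.2) / noise_sd
            scores[side] = stats.truncnorm.ppf(u[side], a_d, b_d, loc=0.8, scale=noise_sd)
            scores[~side] = stats.truncnorm.ppf(u[~side], a_o, b_o, loc=0.2, scale=noise_sd)
            # keep the ordered side strictly below the inclusive 0.5 threshold
            scores[~side] = np.minimum(scores[~side], np.nextafter(0.5, 0.0))
        for i, pid in enumerate(ids):
            tracks.append(
                ResidueScoreTrack(pid, f"pred{p + 1}", scores[offsets[i] : offsets[i + 1]].copy())
            )
    return tracks


def generate_ppi(
    proteins: Sequence[ProteinRecord],
    truth_class: Mapping[str, DisorderClass],
    degree_baseline: float,
    degree_disorder_effect: float,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, str]]:
    """Degree-structured undirected edges via configuration-style pairing.

    Every protein draws a Poisson degree at the baseline mean; TFs of the
    HD truth class draw at baseline + effect.  Stubs are shuffled and
    paired; self-pairs are kept as self-loops and unordered duplicates are
    collapsed.
    """
    if degree_baseline < 0 or degree_baseline + degree_disorder_effect < 0:
        raise SpecValidationError("degree means must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = np.array([p.protein_id for p in proteins])
    if ids.size == 0:
        return []
    lam = np.full(ids.size, float(degree_baseline))
    boosted = np.array(
        [p.is_tf and truth_class[p.protein_id] is DisorderClass.HD for p in proteins]
    )
    lam[boosted] += degree_disorder_effect
    degrees = rng.poisson(lam)
    stubs = np.repeat(np.arange(ids.size), degrees)
    if stubs.size % 2:
        stubs = stubs[:-1]
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    seen: dict[tuple[str, str], None] = {}
    for i, j in pairs:
        a, b = (ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i])
        seen.setdefault((a, b))
    return list(seen)


def generate_proteome(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full synthetic dataset under ``spec``; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ds = SyntheticDataset(spec=spec)
    n = spec.n_proteins
    if n == 0:
        return ds

    width = max(4, len(str(n)))
    ids = [f"SYN{i + 1:0{width}d}" for i in range(n)]
    lengths = rng.integers(spec.length_range[0], spec.length_range[1] + 1, size=n)
    weights = np.array([w for w, _ in spec.dratio_mixture])
    comp = rng.choice(len(spec.dratio_mixture), size=n, p=weights / weights.sum())

    n_tf = int(np.floor(spec.frac_tf * n))
    tf_ids = set(rng.choice(n, size=n_tf, replace=False).tolist()) if n_tf else set()

    truth_is_idp = np.zeros(n, dtype=bool)
    for i, pid in enumerate(ids):
        interval = spec.dratio_mixture[comp[i]][1]
        mask = _plant_blocks(
            int(lengths[i]), interval, rng, spec.idr_block_min, spec.idr_block_mean,
            spec.min_block_gap,
        )
        ds.truth_masks[pid] = mask
        d = float(mask.mean())
        ds.truth_dratio[pid] = d
        cls = classify_disorder(d)
        ds.truth_class[pid] = cls
        truth_is_idp[i] = cls is DisorderClass.HD
        runs = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        ds.truth_intervals[pid] = [
            IDRInterval(int(s) + 1, int(e)) for s, e in zip(runs[::2], runs[1::2])
        ]
        ds.sequences[pid] = "".join(rng.choice(_AMINO_ACIDS, size=int(lengths[i])))

    # pathway memberships: weighted sampling without replacement oversamples
    # true IDPs at the planted odds
    for name, size, odds in zip(
        spec.pathway_names, spec.resolved_pathway_sizes(), spec.planted_enrichment_odds
    ):
        w = np.where(truth_is_idp, odds, 1.0)
        members = rng.choice(n, size=size, replace=False, p=w / w.sum())
        ds.term_map[name] = {ids[m] for m in members}

    # localizations: mostly unique, some diverse, a few conflicting
    pllps_noise = (
        rng.normal(0.0, spec.pllps_noise_sd, size=n) if spec.pllps_noise_sd > 0 else np.zeros(n)
    )
    for i, pid in enumerate(ids):
        n_comp = 1 + int(rng.random() < 0.25) + int(rng.random() < 0.05)
        comps = rng.choice(len(_COMPARTMENTS), size=n_comp, replace=False)
        locs = frozenset(
            (_COMPARTMENTS[c], _SOURCES[int(rng.integers(len(_SOURCES)))]) for c in comps
        )
        conflict = len({c for c, _ in locs}) > 1 and rng.random() < 0.15
        pllps = float(
            np.clip(
                spec.pllps_slope * ds.truth_dratio[pid] + spec.pllps_intercept + pllps_noise[i],
                0.0,
                1.0,
            )
        )
        pathways = frozenset(t for t, members in ds.term_map.items() if pid in members)
        ds.proteins.append(
            ProteinRecord(
                protein_id=pid,
                length=int(lengths[i]),
                is_tf=i in tf_ids,
                pathways=pathways,
                localizations=locs,
                loc_conflict=conflict,
                pllps=pllps,
            )
        )

    ds.tracks = generate_score_tracks(
        ds.truth_masks, spec.n_predictors, spec.predictor_noise_sd,
        spec.predictor_agreement, rng,
    )
    ds.edges = generate_ppi(
        ds.proteins, ds.truth_class, spec.degree_baseline, spec.degree_disorder_effect, rng
    )
    return ds


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset as plain-text files; round-trips through the readers.

    Emits: proteome FASTA, long-format score TSV, annotation TSV, edge TSV,
    pLLPS TSV and a truth JSON.  Returns the path of each artifact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteome.fasta",
        "scores": directory / "scores.tsv",
        "annotations": directory / "annotations.tsv",
        "edges": directory / "edges.tsv",
        "pllps": directory / "pllps.tsv",
        "truth": directory / "truth.json",
    }
    try:
        with open(paths["fasta"], "w") as fh:
            for pid in ds.protein_ids:
                fh.write(f">{pid}\n")
                seq = ds.sequences[pid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["scores"], "w") as fh:
            fh.write("protein_id\tposition\tpredictor\tscore\n")
            for t in ds.tracks:
                for pos, s in enumerate(t.scores, start=1):
                    fh.write(f"{t.protein_id}\t{pos}\t{t.predictor_id}\t{float(s)!r}\n")
        with open(paths["annotations"], "w") as fh:
            fh.write("protein_id\tis_tf\tpathways\tlocalizations\tloc_conflict\n")
            for p in ds.proteins:
                pathways = ";".join(sorted(p.pathways))
                locs = ";".join(f"{c}:{s}" for c, s in sorted(p.localizations))
                fh.write(f"{p.protein_id}\t{int(p.is_tf)}\t{pathways}\t{locs}\t{int(p.loc_conflict)}\n")
        with open(paths["edges"], "w") as fh:
            fh.write("id_a\tid_b\n")
            for a, b in ds.edges:
                fh.write(f"{a}\t{b}\n")
        with open(paths["pllps"], "w") as fh:
            fh.write("protein_id\tpllps\n")
            for p in ds.proteins:
                fh.write(f"{p.protein_id}\t{p.pllps!r}\n")
        truth = {
            "seed": ds.spec.seed,
            "dratio": ds.truth_dratio,
            "class": {pid: cls.name for pid, cls in ds.truth_class.items()},
            "intervals": {
                pid: [[iv.start, iv.end] for iv in ivs] for pid, ivs in ds.truth_intervals.items()
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths
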