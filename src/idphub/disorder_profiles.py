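"""Per-protein structural-disorder computations.

This module holds the quantitative core of the analysis: converting
per-residue disorder probabilities into binary order/disorder calls,
deriving the disorder ratio (D_ratio, the fraction of residues called
disordered), extracting intrinsically disordered regions (IDRs, maximal
runs of at least ``min_window`` consecutive disordered residues),
combining several predictors into a consensus mask, and assigning each
protein to a disorder class (ORDERED / LD / MD / HD).

Conventions
-----------
* A residue is *disordered* when its score is greater than or equal to
  the threshold (default 0.5, inclusive).
* IDR coordinates are 1-based and inclusive on both ends.  The on-disk
  BED-like export uses 0-based half-open coordinates; both dialects are
  stated in the file headers written here.
* Disorder-class bands form a total, non-overlapping partition of
  [0, 1]:  ORDERED (d <= 0.1) < LD (0.1 < d < 0.3) < MD (0.3 <= d < 0.5)
  < HD (d >= 0.5).  A protein of class HD is an intrinsically disordered
  protein (IDP).
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ResidueScoreTrack",
    "BinaryMask",
    "IDRInterval",
    "DisorderSummary",
    "ConsensusParams",
    "DisorderClass",
    "binarize_track",
    "disorder_ratio",
    "mean_disorder_score",
    "extract_idrs",
    "consensus_mask",
    "classify_disorder",
    "summarize_protein",
    "read_score_table",
    "write_summary_table",
    "write_idr_bed",
]

CONSENSUS_ID = "consensus"

#: Residue-level disorder call threshold (score >= threshold is disordered).
RESIDUE_THRESHOLD = 0.5

#: Minimum IDR length in residues (long disordered regions only, to avoid
#: flexible linkers/loops of globular proteins).
MIN_IDR_WINDOW = 30


class DisorderClass(enum.IntEnum):
    """Disorder-ratio band of a protein; ordering reflects increasing disorder."""

    ORDERED = 0
    LD = 1
    MD = 2
    HD = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class ResidueScoreTrack:
    """One predictor's per-residue disorder probabilities for one protein."""

    protein_id: str
    predictor_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(
                f"track {self.protein_id}/{self.predictor_id}: scores must be "
                "a non-empty 1-D array"
            )
        if np.any((self.scores < 0.0) | (self.scores > 1.0)):
            raise ValueError(
                f"track {self.protein_id}/{self.predictor_id}: scores outside [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class BinaryMask:
    """Order/disorder call per residue (True = disordered)."""

    protein_id: str
    predictor_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError(
                f"mask {self.protein_id}/{self.predictor_id}: states must be "
                "a non-empty 1-D array"
            )

    def __len__(self) -> int:
        return int(self.states.size)


@dataclass(frozen=True, order=True)
class IDRInterval:
    """1-based inclusive residue interval of one IDR."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusParams:
    """Parameters of the multi-predictor consensus.

    ``agreement_fraction`` is the minimum fraction of predictors calling a
    residue disordered (default 5/8, as in majority-style consensus
    predictors); ``morph_radius`` is the half-width of the structuring
    element used for morphological closing-then-opening; raw disordered
    regions shorter than ``min_region`` are discarded.
    """

    agreement_fraction: float = 0.625
    morph_radius: int = 3
    min_region: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.agreement_fraction <= 1.0):
            raise ValueError("agreement_fraction must be in (0, 1]")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be >= 0")
        if self.min_region < 1:
            raise ValueError("min_region must be >= 1")


@dataclass
class DisorderSummary:
    """Per-protein derived disorder quantities."""

    protein_id: str
    predictor_id: str
    mean_score: float
    d_ratio: float
    idr_intervals: list[IDRInterval] = field(default_factory=list)
    disorder_class: DisorderClass = DisorderClass.ORDERED

    @property
    def idr_count(self) -> int:
        return len(self.idr_intervals)

    @property
    def is_idp(self) -> bool:
        """IDP = intrinsically disordered protein, i.e. class HD (d_ratio >= 0.5)."""
        return self.disorder_class is DisorderClass.HD


def binarize_track(track: ResidueScoreTrack, threshold: float = RESIDUE_THRESHOLD) -> BinaryMask:
    """Call each residue disordered iff its score >= ``threshold`` (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return BinaryMask(track.protein_id, track.predictor_id, track.scores >= threshold)


def disorder_ratio(mask: BinaryMask) -> float:
    """Fraction of residues called disordered (the protein's D_ratio)."""
    return float(np.count_nonzero(mask.states)) / len(mask)


def mean_disorder_score(track: ResidueScoreTrack) -> float:
    """Arithmetic mean of the per-residue disorder scores."""
    return float(np.mean(track.scores))


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of a boolean array as 0-based half-open (start, stop)."""
    padded = np.concatenate(([False], states, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def extract_idrs(mask: BinaryMask, min_window: int = MIN_IDR_WINDOW) -> list[IDRInterval]:
    """Maximal runs of consecutive disordered residues of length >= ``min_window``.

    Returned as 1-based inclusive intervals in ascending order.
    """
    if min_window < 1:
        raise ValueError("min_window must be >= 1")
    return [
        IDRInterval(start + 1, stop)
        for start, stop in _runs(mask.states)
        if stop - start >= min_window
    ]


def _structure(radius: int) -> np.ndarray:
    return np.ones(2 * radius + 1, dtype=bool)


def _close_open(states: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing then opening with a centered element of half-width
    ``radius``.

    The mask is treated as embedded in an infinite ordered background: it is
    zero-padded by twice the radius before the operations and cropped after,
    so the composition is the identity on isolated runs longer than the
    element, including runs touching the protein termini.
    """
    if radius == 0:
        return states
    s = _structure(radius)
    pad = 2 * radius
    padded = np.pad(states, pad)
    closed = ndimage.binary_closing(padded, s)
    opened = ndimage.binary_opening(closed, s)
    return opened[pad:-pad]


def consensus_mask(masks: Sequence[BinaryMask], params: ConsensusParams | None = None) -> BinaryMask:
    """Combine per-predictor masks into one consensus mask.

    A residue is raw-consensus disordered when the fraction of input masks
    calling it disordered is >= ``params.agreement_fraction``; the raw mask
    is then smoothed by morphological closing followed by opening, and
    surviving disordered regions shorter than ``params.min_region`` are
    removed.
    """
    params = params or ConsensusParams()
    if not masks:
        raise ValueError("consensus_mask requires at least one mask")
    lengths = {len(m) for m in masks}
    if len(lengths) != 1:
        offending = ", ".join(f"{m.predictor_id}({len(m)})" for m in masks)
        raise ValueError(f"masks have mismatched lengths: {offending}")
    votes = np.mean([m.states for m in masks], axis=0)
    raw = votes >= params.agreement_fraction
    smooth = _close_open(raw, params.morph_radius)
    out = smooth.copy()
    for start, stop in _runs(smooth):
        if stop - start < params.min_region:
            out[start:stop] = False
    return BinaryMask(masks[0].protein_id, CONSENSUS_ID, out)


def classify_disorder(d_ratio: float) -> DisorderClass:
    """Assign the disorder-ratio band.

    ORDERED if d <= 0.1; LD if 0.1 < d < 0.3; MD if 0.3 <= d < 0.5;
    HD (the IDP class) if d >= 0.5.
    """
    if not (0.0 <= d_ratio <= 1.0):
        raise ValueError(f"d_ratio out of range: {d_ratio}")
    if d_ratio <= 0.1:
        return DisorderClass.ORDERED
    if d_ratio < 0.3:
        return DisorderClass.LD
    if d_ratio < 0.5:
        return DisorderClass.MD
    return DisorderClass.HD


def summarize_protein(
    tracks: Sequence[ResidueScoreTrack],
    reference_predictor: str = CONSENSUS_ID,
    min_window: int = MIN_IDR_WINDOW,
    threshold: float = RESIDUE_THRESHOLD,
    consensus_params: ConsensusParams | None = None,
) -> DisorderSummary:
    """Derive the per-protein disorder summary from one protein's score tracks.

    ``reference_predictor`` selects the mask used for D_ratio, IDRs and the
    class: either a predictor id present among ``tracks`` or ``"consensus"``
    (the default), in which case all tracks vote.  The mean score is the mean
    of the reference track, or the grand mean over all tracks for the
    consensus reference.
    """
    if not tracks:
        raise ValueError("summarize_protein requires at least one track")
    protein_id = tracks[0].protein_id
    if any(t.protein_id != protein_id for t in tracks):
        raise ValueError("all tracks must belong to the same protein")

    if reference_predictor == CONSENSUS_ID:
        masks = [binarize_track(t, threshold) for t in tracks]
        mask = consensus_mask(masks, consensus_params)
        mean_score = float(np.mean([t.scores for t in tracks]))
    else:
        matching = [t for t in tracks if t.predictor_id == reference_predictor]
        if not matching:
            known = sorted({t.predictor_id for t in tracks})
            raise KeyError(
                f"unknown reference predictor {reference_predictor!r}; "
                f"tracks present: {known}"
            )
        track = matching[0]
        mask = binarize_track(track, threshold)
        mean_score = mean_disorder_score(track)

    d_ratio = disorder_ratio(mask)
    return DisorderSummary(
        protein_id=protein_id,
        predictor_id=reference_predictor,
        mean_score=mean_score,
        d_ratio=d_ratio,
        idr_intervals=extract_idrs(mask, min_window),
        disorder_class=classify_disorder(d_ratio),
    )


# ---------------------------------------------------------------------------
# I/O: long-format score table and summary exports
# ---------------------------------------------------------------------------

def read_score_table(path) -> list[ResidueScoreTrack]:
    """Read a long-format score TSV (protein_id, position, predictor, score).

    Positions are 1-based and must be contiguous from 1 for every
    (protein, predictor) pair.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"protein_id", "position", "predictor", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table {path}: missing columns {sorted(missing)}")
    tracks: list[ResidueScoreTrack] = []
    for (pid, pred), grp in df.groupby(["protein_id", "predictor"], sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"score table {path}: non-contiguous positions for {pid}/{pred}")
        tracks.append(ResidueScoreTrack(str(pid), str(pred), grp["score"].to_numpy()))
    return tracks


def group_tracks_by_protein(tracks: Iterable[ResidueScoreTrack]) -> dict[str, list[ResidueScoreTrack]]:
    """Group tracks by protein id, preserving first-seen order."""
    out: dict[str, list[ResidueScoreTrack]] = {}
    for t in tracks:
        out.setdefault(t.protein_id, []).append(t)
    return out


def summaries_to_frame(summaries: Sequence[DisorderSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in summaries],
            "predictor": [s.predictor_id for s in summaries],
            "mean_score": [s.mean_score for s in summaries],
            "d_ratio": [s.d_ratio for s in summaries],
            "idr_count": [s.idr_count for s in summaries],
            "class": [s.disorder_class.name for s in summaries],
        }
    )


def write_summary_table(summaries: Sequence[DisorderSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-protein disorder summary; IDR coordinates elsewhere are 1-based inclusive\n")
        summaries_to_frame(summaries).to_csv(fh, sep="\t", index=False)


def write_idr_bed(summaries: Sequence[DisorderSummary], path) -> None:
    """Write IDR intervals as BED-like TSV (0-based half-open on disk)."""
    with open(path, "w") as fh:
        fh.write("# BED-like: start is 0-based, end exclusive (half-open on disk; "
                 "summaries use 1-based inclusive)\n")
        fh.write("protein_id\tstart\tend\n")
        for s in summaries:
            for iv in s.idr_intervals:
                fh.write(f"{s.protein_id}\t{iv.start - 1}\t{iv.end}\n")
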