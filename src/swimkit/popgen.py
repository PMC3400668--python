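"""Kimura 2-parameter distances and population summaries.

For a pair of aligned sequences with transition proportion P and
transversion proportion Q over the sites valid in both (pairwise deletion of
gaps and ambiguous bases), the K2P distance is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

in expected substitutions per site.  Divergences large enough to make either
logarithm argument non-positive are saturated: the distance is undefined and
flagged rather than extrapolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError, SaturationError

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


@dataclass
class AlignedSequences:
    """An aligned nucleotide data set with per-sequence population labels."""

    ids: list[str]
    sequences: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences) or len(self.ids) != len(self.groups):
            raise InvalidParameterError("ids, sequences and groups must align")
        if len(self.sequences) < 2:
            raise InsufficientDataError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InvalidParameterError("all sequences must have equal length")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class PairwiseDiff:
    """Site-pattern proportions behind one pairwise distance."""

    P: float  # transitions / valid sites
    Q: float  # transversions / valid sites
    valid_sites: int


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances; NaN marks saturated pairs."""

    ids: list[str]
    d: np.ndarray  # (n, n), zero diagonal

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def count_differences(seq1: str, seq2: str) -> PairwiseDiff:
    """Transition/transversion proportions under pairwise deletion."""
    if len(seq1) != len(seq2):
        raise InvalidParameterError("sequences must have equal length")
    valid = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _VALID or b not in _VALID:
            continue  # gap or ambiguity in either sequence: site dropped
        valid += 1
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if valid == 0:
        raise InsufficientDataError("no valid sites shared by the pair")
    return PairwiseDiff(P=ts / valid, Q=tv / valid, valid_sites=valid)


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"divergence saturated (P={P:.4f}, Q={Q:.4f}); K2P distance undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(seq1: str, seq2: str) -> tuple[float, PairwiseDiff]:
    """K2P distance (substitutions/site) and its site-pattern summary."""
    diff = count_differences(seq1, seq2)
    return k2p_from_pq(diff.P, diff.Q), diff


def pairwise_matrix(aln: AlignedSequences) -> DistanceMatrix:
    """All pairwise K2P distances; saturated pairs become NaN with a warning."""
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij, _ = k2p_distance(aln.sequences[i], aln.sequences[j])
            except SaturationError:
                warnings.warn(
                    f"saturated pair ({aln.ids[i]}, {aln.ids[j]}); distance set to NaN",
                    stacklevel=2,
                )
                dij = float("nan")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=list(aln.ids), d=d)


@dataclass
class GroupDistanceSummary:
    """Within-group mean distances plus overall pairwise statistics."""

    within: dict[str, float]  # NaN flags groups of size 1
    between: dict[tuple[str, str], float]
    overall_mean: float
    overall_min: float
    overall_max: float


def group_mean_distances(dm: DistanceMatrix, groups: list[str]) -> GroupDistanceSummary:
    """Within- and between-group mean K2P distances and overall summaries.

    Every sequence must carry a group label.  A group with a single member
    has no intra-group pair; its within-group mean is NaN (flagged), not 0.
    """
    n = dm.d.shape[0]
    if len(groups) != n:
        raise InvalidParameterError("one group label per sequence required")
    labels = sorted(set(groups))
    garr = np.asarray(groups)
    within: dict[str, float] = {}
    between: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(n, k=1)
    pair_d = dm.d[iu, ju]
    for g in labels:
        mask = (garr[iu] == g) & (garr[ju] == g)
        within[g] = float(np.nanmean(pair_d[mask])) if mask.any() else float("nan")
    for a_i, ga in enumerate(labels):
        for gb in labels[a_i + 1:]:
            mask = ((garr[iu] == ga) & (garr[ju] == gb)) | ((garr[iu] == gb) & (garr[ju] == ga))
            between[(ga, gb)] = float(np.nanmean(pair_d[mask])) if mask.any() else float("nan")
    return GroupDistanceSummary(
        within=within,
        between=between,
        overall_mean=float(np.nanmean(pair_d)),
        overall_min=float(np.nanmin(pair_d)),
        overall_max=float(np.nanmax(pair_d)),
    )


def pooled_within_distance(dm: DistanceMatrix, groups: list[str], exclude: str) -> float:
    """Mean pairwise distance among all sequences *not* in ``exclude``.

    Mirrors the field convention of contrasting one divergent population's
    within-group mean against the pooled remainder.
    """
    keep = [i for i, g in enumerate(groups) if g != exclude]
    if len(keep) < 2:
        raise InsufficientDataError("fewer than 2 sequences outside the excluded group")
    sub = dm.d[np.ix_(keep, keep)]
    iu, ju = np.triu_indices(len(keep), k=1)
    return float(np.nanmean(sub[iu, ju]))
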