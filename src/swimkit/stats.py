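"""Inferential layer: correlations, unbalanced factorial ANOVA, Duncan test.

Three tools used to relate habitat to phenotype:

* Pearson correlation with the exact two-sided p-value from the t transform
  t = r sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom;
* fixed-effects factorial ANOVA on unbalanced designs, including designs
  with a structurally missing cell (e.g. no upper-reach tributary site):
  terms are sum-to-zero coded, columns made collinear by missing cells are
  detected and dropped (and reported), and each term is tested Type-III
  style by comparing the full model against the model without that term;
* Duncan's multiple range test with compact letter displays, using
  studentized-range least significant ranges at the span-adjusted level
  1 - (1-alpha)^(p-1).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    InestimableTermError,
    InsufficientDataError,
    InvalidParameterError,
)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    r: float
    n: int
    p: float


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r via the t transform, n-2 df.

    Symmetric in the sign of r; |r| >= 1 is treated as the boundary p -> 0.
    """
    if n < 3:
        raise InsufficientDataError("need n >= 3 for a correlation p-value")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(sps.t.sf(t, n - 2))


def pearson_with_p(x, y) -> CorrResult:
    """Sample Pearson coefficient with its exact two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need n >= 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return CorrResult(r=r, n=n, p=p_from_r(r, n))


# ---------------------------------------------------------------------------
# Factorial ANOVA on unbalanced / missing-cell designs
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-term F table plus residual line and any dropped interaction contrasts."""

    table: pd.DataFrame  # index: term; columns: df, ss, F, p
    residual_df: int
    residual_ss: float
    dropped_contrasts: list[str] = field(default_factory=list)


def _sum_coding(levels: list) -> dict:
    """Sum-to-zero (deviation) coding: L levels -> L-1 contrast columns."""
    m = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        if i < m - 1:
            v = np.zeros(m - 1)
            v[i] = 1.0
        else:
            v = -np.ones(m - 1)
        rows[lev] = v
    return rows


def _term_matrix(df: pd.DataFrame, term: tuple[str, ...], codings: dict) -> np.ndarray:
    """Model-matrix columns for one term: products of the factors' codings."""
    mats = []
    for fac in term:
        coding = codings[fac]
        mats.append(np.vstack([coding[v] for v in df[fac]]))
    cols = mats[0]
    for m in mats[1:]:
        cols = np.einsum("ij,ik->ijk", cols, m).reshape(len(df), -1)
    return cols


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    max_order: int | None = None,
) -> AnovaResult:
    """Fixed-effects ANOVA with all interactions up to ``max_order``.

    Handles unbalanced designs and structurally missing cells: model columns
    are sum-to-zero coded; interaction columns rendered collinear by missing
    cells are dropped (listed in ``dropped_contrasts``); each term's F is a
    full-vs-reduced model comparison against the residual mean square.
    A term whose columns are all inestimable raises
    :class:`InestimableTermError` naming the missing cells.
    """
    if not 2 <= len(factors) <= 3:
        raise InvalidParameterError("factorial_anova supports 2 or 3 factors")
    df = table.dropna(subset=[response, *factors]).reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    n = len(df)
    codings = {}
    for fac in factors:
        levels = sorted(df[fac].unique().tolist())
        if len(levels) < 2:
            raise InvalidParameterError(f"factor {fac!r} has fewer than 2 observed levels")
        codings[fac] = _sum_coding(levels)

    if max_order is None:
        max_order = len(factors)
    terms: list[tuple[str, ...]] = []
    for order in range(1, max_order + 1):
        terms.extend(itertools.combinations(factors, order))

    # missing cells of the full factorial, for error messages
    full_cells = set(itertools.product(*[sorted(df[f].unique()) for f in factors]))
    seen_cells = set(map(tuple, df[factors].itertuples(index=False, name=None)))
    missing_cells = sorted(full_cells - seen_cells)

    # assemble columns, dropping any that are collinear with what came before
    columns: list[np.ndarray] = [np.ones(n)]
    col_term: list[tuple[str, ...] | None] = [None]
    dropped: list[str] = []
    basis = np.ones((n, 1)) / math.sqrt(n)
    for term in terms:
        cols = _term_matrix(df, term, codings)
        kept_any = False
        for j in range(cols.shape[1]):
            v = cols[:, j]
            r = v - basis @ (basis.T @ v)
            if np.linalg.norm(r) > 1e-8 * max(np.linalg.norm(v), 1.0):
                columns.append(v)
                col_term.append(term)
                basis = np.hstack([basis, (r / np.linalg.norm(r))[:, None]])
                kept_any = True
            else:
                dropped.append(f"{':'.join(term)}[{j}]")
        if not kept_any:
            raise InestimableTermError(
                f"term {':'.join(term)} is not estimable; missing cells: {missing_cells}"
            )

    x_full = np.column_stack(columns)
    rank_full = x_full.shape[1]  # columns were kept only if independent
    df_res = n - rank_full
    if df_res <= 0:
        raise InsufficientDataError("no residual degrees of freedom")

    sse_full = _sse(x_full, y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    mse = sse_full / df_res

    rows = []
    for term in terms:
        mask = [t != term for t in col_term]
        df_term = mask.count(False)
        x_red = x_full[:, mask]
        if ss_total <= 1e-12 * max(1.0, float(y @ y)):
            f_val, p_val, ss_term = 0.0, 1.0, 0.0
        else:
            ss_term = max(_sse(x_red, y) - sse_full, 0.0)
            if mse == 0:
                f_val = 0.0 if ss_term == 0 else math.inf
                p_val = 1.0 if ss_term == 0 else 0.0
            else:
                f_val = (ss_term / df_term) / mse
                p_val = float(sps.f.sf(f_val, df_term, df_res))
        rows.append(
            {"term": ":".join(term), "df": df_term, "ss": ss_term, "F": f_val, "p": p_val}
        )

    out = pd.DataFrame(rows).set_index("term")
    return AnovaResult(
        table=out, residual_df=df_res, residual_ss=sse_full, dropped_contrasts=dropped
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class DuncanResult:
    """Ranked means, least significant ranges and the compact letter display."""

    letters: dict  # group -> letter string
    means: pd.Series  # group means, descending
    mse: float
    df_resid: int
    critical_ranges: dict  # span p -> least significant range


@functools.lru_cache(maxsize=4096)
def _duncan_q(p_span: int, df: int, alpha: float) -> float:
    """Studentized-range quantile at the Duncan-adjusted level (cached: the
    quantile is expensive and identical across same-layout data sets)."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    return float(sps.studentized_range.ppf(1.0 - alpha_p, p_span, df))


def _duncan_lsr(p_span: int, df: int, mse: float, n_h: float, alpha: float) -> float:
    """Least significant range for a span of ``p_span`` ranked means."""
    return _duncan_q(p_span, df, alpha) * math.sqrt(mse / n_h)


def duncan_letters(
    groups, values, alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test with a compact letter display.

    Group means are ranked and every stretch of ``p`` consecutive ranked
    means is compared against its least significant range
    ``q(1-(1-alpha)^(p-1); p, df) * sqrt(MSE / n_h)`` (``n_h`` the harmonic
    mean group size, MSE the pooled within-group mean square).  A stretch
    whose extremes do not differ is homogeneous, as is any stretch inside a
    homogeneous one (the standard protection rule).  Groups sharing no
    letter differ at ``alpha``.
    """
    s = pd.Series(np.asarray(values, dtype=float), index=list(groups))
    counts = s.groupby(level=0).count()
    if len(counts) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"groups with fewer than 2 observations: {small}")
    means = s.groupby(level=0).mean().sort_values(ascending=False)
    k = len(means)
    n_total = int(counts.sum())
    df_res = n_total - k
    sse = float(((s - s.groupby(level=0).transform("mean")) ** 2).sum())
    mse = sse / df_res
    n_h = k / float((1.0 / counts).sum())

    lsr = {p: _duncan_lsr(p, df_res, mse, n_h, alpha) for p in range(2, k + 1)}

    m = means.to_numpy()
    homogeneous: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in homogeneous):
                continue  # protected by a containing homogeneous stretch
            if m[i] - m[j] <= lsr[span]:
                homogeneous.append((i, j))

    # maximal homogeneous stretches, plus singleton letters for uncovered groups
    maximal = [
        (a, b)
        for a, b in homogeneous
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in homogeneous)
    ]
    for i in range(k):
        if not any(a <= i <= b for a, b in maximal):
            maximal.append((i, i))
    maximal.sort()

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in means.index}
    for letter_idx, (a, b) in enumerate(maximal):
        for pos in range(a, b + 1):
            letters[means.index[pos]] += alphabet[letter_idx % len(alphabet)]

    return DuncanResult(
        letters=letters, means=means, mse=mse, df_resid=df_res, critical_ranges=lsr
    )
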