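"""Overlap-fraction statistics and cohort summaries.

The central quantity is the overlap fraction

    OF(A | B) = 100 * |A ∩ B| / |B|,

the percentage of the reference volume B contained in A (voxel counts on a
shared grid).  For the response analysis, A is a baseline subvolume (Pre40%
or Pre50% of SUVmax) and B is a post-treatment subvolume (Post60–90%)
propagated to the planning grid, or the clinician GTV when assessing
coverage.  Percentages are kept at full precision internally and rounded
half-up to one decimal only for table output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BinaryMask

PRE_KEYS = ("Pre40%", "Pre50%")
POST_KEYS = ("Post90%", "Post80%", "Post70%", "Post60%")
OVERLAP_KEYS = tuple(
    f"{pre.rstrip('%')[:5]}|{post.rstrip('%')}" for pre in PRE_KEYS for post in POST_KEYS
)
# -> "Pre40|Post90", ..., "Pre50|Post60"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table convention), e.g. 83.25 -> 83.3."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_grid(b):
        raise ValueError("masks are not on the same grid")


def intersection_count(a: BinaryMask, b: BinaryMask) -> int:
    _check_same_grid(a, b)
    return int(np.count_nonzero(a.data & b.data))


def overlap_fraction(a: BinaryMask, b: BinaryMask) -> float:
    """Percentage of reference mask ``b`` covered by ``a``: 100*|a∩b|/|b|."""
    _check_same_grid(a, b)
    n_b = b.count
    if n_b == 0:
        raise ValueError("empty reference volume")
    return 100.0 * intersection_count(a, b) / n_b


def gtv_coverage(pre: BinaryMask, gtv: BinaryMask) -> float:
    """Percentage of the GTV covered by a baseline subvolume."""
    if gtv.count == 0:
        raise ValueError("empty GTV")
    return overlap_fraction(pre, gtv)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|a∩b|/(|a|+|b|); consistency cross-check for OF."""
    _check_same_grid(a, b)
    denom = a.count + b.count
    if denom == 0:
        raise ValueError("both masks empty")
    return 2.0 * intersection_count(a, b) / denom


@dataclass(frozen=True)
class CohortSummary:
    mean: float
    min: float
    max: float
    median: float


def cohort_summary(values) -> CohortSummary:
    """Mean, range and median of a cohort column.

    Median uses the midpoint-of-two-central-values convention for even n.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty value list")
    s = np.sort(arr)
    n = arr.size
    median = float(s[n // 2]) if n % 2 else float((s[n // 2 - 1] + s[n // 2]) / 2)
    return CohortSummary(
        mean=float(arr.mean()), min=float(s[0]), max=float(s[-1]), median=median
    )


@dataclass(frozen=True)
class PairedTTest:
    t: float
    df: int
    p_two_sided: float


def paired_t_test(pre, post) -> PairedTTest:
    """Two-tailed paired t-test on matched measurements (e.g. SUVmax pre/post).

    t = mean(d) / (sd(d)/sqrt(n)) with d = pre - post, df = n - 1, p from the
    Student t distribution.
    """
    pre = np.asarray(list(pre), dtype=np.float64)
    post = np.asarray(list(post), dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical measurements: no evidence of change
            return PairedTTest(t=0.0, df=n - 1, p_two_sided=1.0)
        raise ValueError("zero-variance differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTTest(t=t, df=n - 1, p_two_sided=p)


def build_overlap_table(rows: dict) -> pd.DataFrame:
    """Assemble per-patient overlap fractions plus cohort summary rows.

    ``rows`` maps patient id -> {overlap key -> percent}.  Appends Mean, Min,
    Max and Median rows (computed at full precision, rounded half-up to one
    decimal, matching table formatting).
    """
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[k for k in OVERLAP_KEYS if k in df.columns])
    summary = {}
    for stat in ("Mean", "Min", "Max", "Median"):
        summary[stat] = {
            col: round_half_up(getattr(cohort_summary(df[col].dropna()), stat.lower()))
            for col in df.columns
        }
    out = pd.concat([df, pd.DataFrame.from_dict(summary, orient="index")])
    out.index.name = "Patient"
    return out
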