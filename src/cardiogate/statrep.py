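"""Agreement and comparison statistics for the gating comparison.

Bland-Altman limits of agreement, an exact Wilcoxon matched-pairs test
(zeros dropped, midranks for ties, full sign-assignment enumeration for
small samples), the paired t-test, consensus-score table summaries, and
retrospective CINE phase arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "ScoreTable",
    "BlandAltmanResult",
    "PairedTestResult",
    "bland_altman",
    "wilcoxon_matched_pairs",
    "paired_t_test",
    "summarize_scores",
    "cine_phase_duration",
    "load_table2",
    "round_half_up",
]

MODALITIES = ("ACT", "ECG", "POX")
PHASES = ("end-diastole", "end-systole")
_SCORE_COLUMNS = {
    ("ACT", "end-diastole"): "act_ed", ("ECG", "end-diastole"): "ecg_ed",
    ("POX", "end-diastole"): "pox_ed", ("ACT", "end-systole"): "act_es",
    ("ECG", "end-systole"): "ecg_es", ("POX", "end-systole"): "pox_es",
}

EXACT_ENUMERATION_LIMIT = 15


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.35 -> 2.4), matching print precision."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ScoreTable:
    """Per-subject consensus image-quality scores (0-3 scale)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _SCORE_COLUMNS.values() if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"score table missing columns {missing}")
        vals = self.frame[list(_SCORE_COLUMNS.values())].to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 3):
            raise ValidationError("scores must lie in [0, 3]")

    @property
    def subjects(self):
        return self.frame["subject"].tolist() if "subject" in self.frame else list(
            range(1, len(self.frame) + 1))

    def scores(self, modality: str, phase: str) -> np.ndarray:
        return self.frame[_SCORE_COLUMNS[(modality, phase)]].to_numpy(dtype=float)


def load_table2(path=None) -> ScoreTable:
    """Consensus image-quality scores (packaged fixture by default)."""
    if path is None:
        from importlib.resources import files
        path = files("cardiogate.data") / "table2.csv"
    return ScoreTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pairs: np.ndarray   # (mean, difference) rows


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement: bias and mean +/- 1.96 SD limits of the
    pairwise differences ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if a.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least two pairs")
    diffs = a - b
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    pairs = np.column_stack([(a + b) / 2.0, diffs])
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, sd_diff=sd, pairs=pairs)


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    test: str
    statistic: float
    p_two_sided: float
    n_effective: int

    def __post_init__(self):
        if not 0 <= self.p_two_sided <= 1:
            raise ValidationError("p-value must lie in [0, 1]")


def _signed_rank_p_exact(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    (possibly tied) rank multiset."""
    n = ranks.size
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    sums = masks @ ranks
    total = ranks.sum()
    w_min = min(w_plus, total - w_plus)
    eps = 1e-9
    p = 2.0 * np.mean(sums <= w_min + eps)
    return min(float(p), 1.0)


def wilcoxon_matched_pairs(x, y) -> PairedTestResult:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped, tied absolute differences get midranks.
    For n <= 15 nonzero pairs the two-sided p is exact (full enumeration of
    sign assignments, retaining the tied rank multiset); larger samples use
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise InsufficientDataError("need at least two pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult("wilcoxon_matched_pairs", 0.0, 1.0, 0)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= EXACT_ENUMERATION_LIMIT:
        p = _signed_rank_p_exact(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    return PairedTestResult("wilcoxon_matched_pairs", statistic, p, n)


def paired_t_test(x, y) -> PairedTestResult:
    """Standard paired t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise InsufficientDataError("need at least two pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateVarianceError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return PairedTestResult("paired_t", float(res.statistic), float(res.pvalue), x.size)


class DegenerateVarianceError(InsufficientDataError):
    """All paired differences are identical; the t statistic is undefined."""


# ---------------------------------------------------------------------------
# score summaries and CINE arithmetic
# ---------------------------------------------------------------------------

def summarize_scores(table: ScoreTable) -> dict:
    """Per (modality, phase) mean and sample SD, half-up rounded to one
    decimal (print precision of the summary table)."""
    if len(table.frame) == 0:
        raise ValidationError("empty score table")
    out = {}
    for key in _SCORE_COLUMNS:
        vals = table.scores(*key)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[key] = (round_half_up(float(np.mean(vals))), round_half_up(sd))
    return out


def cine_phase_duration(n_phases: int, heart_rate_bpm: float) -> int:
    """Duration (ms, nearest integer) of one retrospective CINE phase when
    the R-R interval at the given heart rate is split into equal phases."""
    if n_phases < 1 or heart_rate_bpm <= 0:
        raise ValidationError("need n_phases >= 1 and a positive heart rate")
    return int(np.floor((60000.0 / heart_rate_bpm) / n_phases + 0.5))
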