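"""Agreement statistics between a reference arm and mIF-derived cell calls.

Panel validation compares, per tissue core and per marker, the percentage
of positive cells called by a reference modality (chromogenic singleplex
IHC, or ground truth in simulation) against the multiplexed
immunofluorescence result.  The statistics follow standard method-agreement
practice: Spearman rank correlation for the monotone relationship,
Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 x SD of the
paired differences), a fixed 10-percentage-point cell-positivity criterion
per core, Mann-Whitney U for unpaired group comparisons and the paired t
test for paired pipeline comparisons.  Alpha is 0.05 two-tailed throughout
and no multiple-testing correction is applied (noted in the report).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError

__all__ = [
    "spearman_rank",
    "bland_altman",
    "mann_whitney_u",
    "paired_t",
    "positivity_criterion",
    "validate_panel",
    "PairedPositivity",
    "AgreementResult",
    "BlandAltman",
]

ALPHA = 0.05
POSITIVITY_RULE_PP = 10.0  # flag units differing by > 10 percentage points
_EXACT_SPEARMAN_N = 10  # exact permutation p below this n
_EXACT_MWU_MIN_N = 8  # exact enumeration when min group size <= this


def _ranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    The p-value uses exact permutation enumeration for n < 10 and the
    t-approximation otherwise.  Constant input makes r_s undefined: (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ConfigurationError("Spearman correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx, ry = _ranks(x), _ranks(y)
    if np.array_equal(rx, ry):
        rs = 1.0  # identical rankings are exactly concordant
    else:
        rs = float(np.corrcoef(rx, ry)[0, 1])
    if n < _EXACT_SPEARMAN_N:
        # exact two-sided permutation p-value on |r_s|
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rs)
        for perm in itertools.permutations(range(n)):
            r = float(rx_c[list(perm)] @ ry_c) / denom
            count += abs(r) >= obs - 1e-12
            total += 1
        return rs, count / total
    if abs(rs) >= 1.0:
        return rs, 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return rs, float(p)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    within_loa: np.ndarray  # per-point flags
    differences: np.ndarray
    means: np.ndarray


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement: differences d = x - y, bias = mean(d),
    limits of agreement = bias +/- 1.96 x sample SD (n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("x and y must have equal length")
    n = len(x)
    if n < 2:
        raise ConfigurationError("Bland-Altman requires n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    low, high = bias - 1.96 * sd, bias + 1.96 * sd
    within = (d >= low) & (d <= high)
    return BlandAltman(bias, low, high, within, d, (x + y) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for x) with tie-corrected normal approximation for
    large samples and exact enumeration when min(n) <= 8."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigurationError("both samples must be nonempty")
    method = "exact" if min(len(x), len(y)) <= _EXACT_MWU_MIN_N and not _has_ties(x, y) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    allv = np.concatenate([x, y])
    return len(np.unique(allv)) < len(allv)


def paired_t(x, y) -> tuple[float, float]:
    """Classical paired t on differences, two-tailed, df = n - 1.

    Zero-variance differences: zero mean gives (0, 1); nonzero mean gives
    t = +/-inf with p = 0 (degenerate-certainty convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("paired t requires equal-length samples")
    n = len(x)
    if n < 2:
        raise ConfigurationError("paired t requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# positivity criterion and panel-level validation


@dataclass
class PairedPositivity:
    """Per-unit paired %-positive rows for one marker."""

    marker: str
    units: list[str]
    reference_pct: np.ndarray
    test_pct: np.ndarray

    def __post_init__(self) -> None:
        self.reference_pct = np.asarray(self.reference_pct, dtype=float)
        self.test_pct = np.asarray(self.test_pct, dtype=float)
        if self.reference_pct.shape != self.test_pct.shape or len(self.units) != len(
            self.reference_pct
        ):
            raise ConfigurationError("paired positivity rows must align")
        for arr in (self.reference_pct, self.test_pct):
            if np.any((arr < 0) | (arr > 100)):
                raise ConfigurationError("percentages must lie in [0, 100]")


def positivity_criterion(paired: PairedPositivity) -> pd.DataFrame:
    """Flag units whose reference/test positivity differ by > 10 points."""
    diff = np.abs(paired.reference_pct - paired.test_pct)
    return pd.DataFrame(
        {
            "unit": paired.units,
            "marker": paired.marker,
            "reference_pct": paired.reference_pct,
            "test_pct": paired.test_pct,
            "abs_diff_pp": diff,
            "flagged": diff > POSITIVITY_RULE_PP,
        }
    )


@dataclass
class AgreementResult:
    marker: str
    n_units: int
    r_s: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n_flagged: int
    verdict: str
    fraction_within_loa: float = float("nan")
    bias_within_halfwidth: bool = True
    flags: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "n_units": self.n_units,
            "r_s": self.r_s,
            "p_value": self.p_value,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n_flagged_10pp": self.n_flagged,
            "fraction_within_loa": self.fraction_within_loa,
            "bias_within_halfwidth": self.bias_within_halfwidth,
            "verdict": self.verdict,
            "alpha": ALPHA,
            "multiple_testing_correction": "none",
        }


def _positivity_table(labels: pd.Series, units: pd.Series, markers: list[str]) -> pd.DataFrame:
    """% of cells per unit whose class label implies each marker positive."""
    from .phenotyping import label_implies_positive

    rows = {}
    for unit in sorted(units.unique()):
        sel = labels[units == unit]
        n = len(sel)
        rows[unit] = {
            m: (100.0 * sum(label_implies_positive(l, m) for l in sel) / n if n else 0.0)
            for m in markers
        }
    return pd.DataFrame(rows).T  # unit x marker


def validate_panel(
    truth_calls: pd.Series,
    mif_calls: pd.Series,
    units: pd.Series,
    markers: list[str],
) -> dict[str, AgreementResult]:
    """Per-marker agreement between reference and mIF classifications.

    Both call series are class labels indexed like `units` (one row per
    cell).  Per unit and marker the %-positive is derived from the labels;
    each marker is then assessed by Spearman correlation, Bland-Altman
    agreement and the 10-point positivity rule.

    Because the bias is by construction the centre of its own limits of
    agreement, "bias within the 95% limits" is operationalised as
    |bias| < 1.96 x SD (the LoA half-width); the fraction of per-unit
    differences inside the LoA is reported alongside so either reading of
    the acceptance rule can be applied.  Verdict: "validated" iff the
    correlation is positive and significant at alpha and the bias passes
    the half-width rule (a zero-spread, zero-bias comparison passes).
    """
    if not (truth_calls.index.equals(mif_calls.index) and truth_calls.index.equals(units.index)):
        raise ConfigurationError("calls and units must share one index")
    ref = _positivity_table(truth_calls, units, markers)
    test = _positivity_table(mif_calls, units, markers)
    results: dict[str, AgreementResult] = {}
    for m in markers:
        x = ref[m].to_numpy()
        y = test[m].to_numpy()
        unit_ids = [str(u) for u in ref.index]
        if len(x) < 3:
            results[m] = AgreementResult(m, len(x), float("nan"), float("nan"),
                                         float("nan"), float("nan"), float("nan"), 0,
                                         "insufficient units")
            continue
        rs, p = spearman_rank(x, y)
        ba = bland_altman(y, x)  # bias of test relative to reference
        flags = positivity_criterion(PairedPositivity(m, unit_ids, x, y))
        significant = (not math.isnan(p)) and p < ALPHA and rs > 0
        halfwidth = (ba.loa_high - ba.loa_low) / 2.0
        bias_ok = abs(ba.bias) < halfwidth or (halfwidth == 0.0 and ba.bias == 0.0)
        verdict = "validated" if (significant and bias_ok) else "not validated"
        results[m] = AgreementResult(
            m, len(x), rs, p, ba.bias, ba.loa_low, ba.loa_high,
            int(flags["flagged"].sum()), verdict,
            float(ba.within_loa.mean()), bool(bias_ok), flags,
        )
    return results
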