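"""Disproportionality statistics on 2x2 contingency tables.

Implements the four algorithms conventionally used for spontaneous-report
signal detection — reporting odds ratio (ROR), proportional reporting ratio
(PRR), the MHRA criterion (PRR with a Yates-corrected chi-square), and the
BCPNN information component (IC) — together with the conservative composite
rule that declares a signal only when all four algorithms flag the pair
simultaneously and the pair has at least ``min_reports`` reports.

The 2x2 table for a (drug, event) pair against a background of reports is

    =================  ============  ============
                       target event  other events
    =================  ============  ============
    target drug        a             b
    all other drugs    c             d
    =================  ============  ============

All functions accept either scalars or aligned numpy arrays for a, b, c, d
and are fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Columns of a signal table, in fixed output order.
SIGNAL_COLUMNS = [
    "a", "b", "c", "d", "n_reports",
    "ror", "ror_lo", "ror_hi",
    "prr", "prr_lo", "prr_hi",
    "chi2", "ic", "ic025",
    "corrected", "degenerate",
    "ror_pos", "prr_pos", "mhra_pos", "bcpnn_pos", "composite",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one drug-event pair against a defined background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")
        if self.n == 0:
            raise ValueError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c

    @classmethod
    def from_margins(cls, n_drug_event: int, n_drug: int, n_event: int,
                     n_total: int) -> "ContingencyTable":
        """Build the table from the pair count and the three margins."""
        a = n_drug_event
        return cls(a, n_drug - a, n_event - a, n_total - n_drug - n_event + a)


@dataclass(frozen=True)
class SignalResult:
    """Point estimates, interval bounds and flags for one pair."""

    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    corrected: bool
    degenerate: bool
    flags: dict = field(default_factory=dict)
    composite: bool = False

    @property
    def n_reports(self) -> int:
        return self.a


def _asarrays(*cells):
    arrs = [np.asarray(x, dtype=float) for x in cells]
    return np.broadcast_arrays(*arrs)


def ror(a, b, c, d, correction: float = 0.5):
    """Reporting odds ratio with its Wald log-scale 95% CI.

    ROR = ad/bc; CI = exp(ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    Tables with any zero cell get a Haldane–Anscombe ``correction`` added to
    all four cells (returned estimates are then marked corrected by callers).
    """
    a, b, c, d = _asarrays(a, b, c, d)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    shift = np.where(zero, correction, 0.0)
    aa, bb, cc, dd = a + shift, b + shift, c + shift, d + shift
    est = (aa * dd) / (bb * cc)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    lo = est * np.exp(-Z_95 * se)
    hi = est * np.exp(Z_95 * se)
    return est, lo, hi


def prr(a, b, c, d, correction: float = 0.5):
    """Proportional reporting ratio with its Wald log-scale 95% CI.

    PRR = [a/(a+b)] / [c/(c+d)];
    CI = exp(ln PRR ± 1.96 * sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))).
    Zero cells are handled with the same continuity policy as :func:`ror`.
    """
    a, b, c, d = _asarrays(a, b, c, d)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    shift = np.where(zero, correction, 0.0)
    aa, bb, cc, dd = a + shift, b + shift, c + shift, d + shift
    est = (aa / (aa + bb)) / (cc / (cc + dd))
    var = 1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd)
    se = np.sqrt(np.maximum(var, 0.0))
    lo = est * np.exp(-Z_95 * se)
    hi = est * np.exp(Z_95 * se)
    return est, lo, hi


def yates_chi2(a, b, c, d):
    """Yates-continuity-corrected chi-square on the 2x2 table.

    chi2 = sum over cells of (|O − E| − 0.5)^2 / E with expected counts from
    the margins; each cell's term is clamped to 0 when |O − E| < 0.5. Tables
    with a zero margin are degenerate: NaN is returned (callers flag them).
    """
    a, b, c, d = _asarrays(a, b, c, d)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.zeros_like(a)
        for obs, er, ec in ((a, r1, c1), (b, r1, c2), (c, r2, c1), (d, r2, c2)):
            e = er * ec / n
            term = np.maximum(np.abs(obs - e) - 0.5, 0.0) ** 2 / e
            chi2 = chi2 + term
    return np.where(degenerate, np.nan, chi2)


def pearson_chi2(a, b, c, d):
    """Uncorrected Pearson chi-square (available instead of Yates by flag)."""
    a, b, c, d = _asarrays(a, b, c, d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return np.where(degenerate, np.nan, chi2)


def bcpnn_ic(a, b, c, d, variant: str = "noren"):
    """BCPNN information component (bits) and its lower 2.5% bound.

    ``variant="noren"`` (default) uses the closed-form shrinkage observed/
    expected ratio: IC = log2((a + 0.5) / (E + 0.5)) with E = (a+b)(a+c)/N,
    and IC025 = IC − 3.3 (a+0.5)^(−1/2) − 2 (a+0.5)^(−3/2).

    ``variant="bate"`` uses the original Bayesian posterior moment
    approximation with Beta priors (alpha1 = beta1 = 1, gamma11 = 1) and a
    normal-approximation IC025 = E(IC) − 1.96 sd(IC).
    """
    a, b, c, d = _asarrays(a, b, c, d)
    n = a + b + c + d
    if variant == "noren":
        expected = (a + b) * (a + c) / n
        ic = np.log2((a + 0.5) / (expected + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return ic, ic025
    if variant == "bate":
        alpha1 = beta1 = gamma11 = 1.0
        alpha = beta = 2.0
        gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
        ic = np.log2(
            (a + gamma11) * (n + alpha) * (n + beta)
            / ((n + gamma) * (a + b + alpha1) * (a + c + beta1))
        )
        var = (1.0 / np.log(2.0)) ** 2 * (
            (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
            + (n - a - b + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
            + (n - a - c + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
        )
        ic025 = ic - Z_95 * np.sqrt(var)
        return ic, ic025
    raise ValueError(f"unknown BCPNN variant {variant!r}")


def mhra(a, b, c, d, min_reports: int = 3):
    """MHRA criterion: PRR >= 2, Yates chi2 >= 4 and at least 3 reports.

    Returns (prr, chi2, mhra_pos). Degenerate tables (a zero margin) get
    chi2 = NaN and a False flag.
    """
    est, _, _ = prr(a, b, c, d)
    chi2 = yates_chi2(a, b, c, d)
    a_arr = np.asarray(a, dtype=float)
    pos = (est >= 2.0) & np.greater_equal(np.nan_to_num(chi2, nan=-1.0), 4.0) \
        & (a_arr >= min_reports)
    return est, chi2, pos


def compute_signal_table(counts: pd.DataFrame, *, bcpnn_variant: str = "noren",
                         yates: bool = True, min_reports: int = 3) -> pd.DataFrame:
    """Run all four algorithms on a table of a/b/c/d counts.

    ``counts`` must carry integer columns a, b, c, d (one row per drug-event
    pair); any other columns (drug, event, level, stratum ...) are preserved.
    Returns a copy with the :data:`SIGNAL_COLUMNS` appended. Pairs with
    a < ``min_reports`` are reported with all flags and the composite
    suppressed (False), as required by the minimum-report rule.
    """
    out = counts.copy()
    a = out["a"].to_numpy(dtype=float)
    b = out["b"].to_numpy(dtype=float)
    c = out["c"].to_numpy(dtype=float)
    d = out["d"].to_numpy(dtype=float)

    ror_est, ror_lo, ror_hi = ror(a, b, c, d)
    prr_est, prr_lo, prr_hi = prr(a, b, c, d)
    chi2 = yates_chi2(a, b, c, d) if yates else pearson_chi2(a, b, c, d)
    ic, ic025 = bcpnn_ic(a, b, c, d, variant=bcpnn_variant)

    n = a + b + c + d
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    degenerate = ((a + b) == 0) | ((c + d) == 0) | ((a + c) == 0) | ((b + d) == 0)
    enough = a >= min_reports

    ror_pos = enough & (ror_lo > 1.0)
    prr_pos = enough & (prr_lo > 1.0)
    mhra_pos = enough & (prr_est >= 2.0) & \
        np.greater_equal(np.nan_to_num(chi2, nan=-1.0), 4.0)
    bcpnn_pos = enough & (ic025 > 0.0)
    composite = ror_pos & prr_pos & mhra_pos & bcpnn_pos

    out["n_reports"] = out["a"].astype(int)
    out["ror"], out["ror_lo"], out["ror_hi"] = ror_est, ror_lo, ror_hi
    out["prr"], out["prr_lo"], out["prr_hi"] = prr_est, prr_lo, prr_hi
    out["chi2"] = chi2
    out["ic"], out["ic025"] = ic, ic025
    out["corrected"] = corrected
    out["degenerate"] = degenerate
    out["ror_pos"], out["prr_pos"] = ror_pos, prr_pos
    out["mhra_pos"], out["bcpnn_pos"] = mhra_pos, bcpnn_pos
    out["composite"] = composite
    assert n.min() > 0 if len(out) else True
    return out


def evaluate_pair(ct: ContingencyTable, *, bcpnn_variant: str = "noren",
                  min_reports: int = 3) -> SignalResult:
    """Evaluate one contingency table with all four algorithms.

    The composite flag is the conjunction of the four per-algorithm flags
    and requires at least ``min_reports`` reports in the a cell; below that
    the per-algorithm flags are suppressed as well.
    """
    df = compute_signal_table(
        pd.DataFrame({"a": [ct.a], "b": [ct.b], "c": [ct.c], "d": [ct.d]}),
        bcpnn_variant=bcpnn_variant, min_reports=min_reports,
    )
    row = df.iloc[0]
    return SignalResult(
        a=ct.a, b=ct.b, c=ct.c, d=ct.d,
        ror=float(row["ror"]), ror_lo=float(row["ror_lo"]), ror_hi=float(row["ror_hi"]),
        prr=float(row["prr"]), prr_lo=float(row["prr_lo"]), prr_hi=float(row["prr_hi"]),
        chi2=float(row["chi2"]), ic=float(row["ic"]), ic025=float(row["ic025"]),
        corrected=bool(row["corrected"]), degenerate=bool(row["degenerate"]),
        flags={
            "ror_pos": bool(row["ror_pos"]),
            "prr_pos": bool(row["prr_pos"]),
            "mhra_pos": bool(row["mhra_pos"]),
            "bcpnn_pos": bool(row["bcpnn_pos"]),
        },
        composite=bool(row["composite"]),
    )
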