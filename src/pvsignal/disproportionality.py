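"""Disproportionality statistics for drug–event signal detection.

All four estimators operate on the standard 2×2 contingency table of
report counts:

====================  ====================  ===================
.                     target event reports  other event reports
target drug           a                     b
other drugs           c                     d
====================  ====================  ===================

with N = a+b+c+d.  The counting unit is the deduplicated report; each
distinct PT is counted once per report, so ``b`` (and ``d``) count
report–PT pairs and the margins stay internally consistent when reports
carry several reactions.

Estimators and signal criteria
------------------------------
ROR    ad/(bc), Wald CI on the log scale; signal when CI lower ≥ 1 and a ≥ 3.
PRR    [a/(a+b)]/[c/(c+d)], Wald CI; signal when a ≥ 3, CI lower ≥ 1, PRR ≥ 2.
MHRA   PRR coupled with the Pearson χ²; signal when a ≥ 3, PRR > 2, χ² ≥ 4.
BCPNN  information component IC = log2[aN/((a+b)(a+c))] with Bayesian
       expectation E(IC) and variance V(IC); signal when E(IC) − 2√V(IC) > 0.
MGPS   simplified EBGM = aN/((a+c)(a+b)) with a Wald interval (not the full
       DuMouchel gamma-Poisson mixture); signal when EB05 ≥ 2.

Zero cells in b or c make the ratio estimators infinite; no continuity
correction is applied — such tables carry an explicit ``degenerate`` marker
and all flags are forced false (the a ≥ 3 minimum gates the criteria anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import CaseReport, MeddraMap

Z95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a ratio estimate would be infinite or undefined."""
        return self.a == 0 or self.b == 0 or self.c == 0 or self.d == 0


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN beta/Dirichlet priors.

    Defaults are the canonical choices of Bate et al. (1998): uniform cell
    priors (alpha1 = beta1 = gamma11 = 1) with marginal totals
    alpha = beta = 2; the joint prior total gamma is derived from the table
    margins so that the prior is centred on independence.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.alpha1, self.beta1, self.gamma11) <= 0:
            raise ValueError("priors must be strictly positive")

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1)))


DEFAULT_PRIORS = BcpnnPriors()


@dataclass
class SignalScores:
    """All four algorithms' estimates, intervals and flags for one PT."""

    pt: str
    soc: Optional[str]
    a: int
    table: ContingencyTable
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    se_ln_ror: float = math.nan
    prr: float = math.nan
    prr_lo: float = math.nan
    prr_hi: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    e_ic: float = math.nan
    v_ic: float = math.nan
    ic_minus_2sd: float = math.nan
    ebgm: float = math.nan
    eb05: float = math.nan
    eb95: float = math.nan
    flags: dict[str, bool] = field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# table construction


def build_contingency(cohort_reports: Sequence[CaseReport],
                      background_reports: Sequence[CaseReport],
                      target_pt: str) -> ContingencyTable:
    """Report-level 2×2 counts for one PT (distinct PTs per report)."""
    a = sum(1 for r in cohort_reports if target_pt in r.reactions)
    cohort_pairs = sum(len(set(r.reactions)) for r in cohort_reports)
    c = sum(1 for r in background_reports if target_pt in r.reactions)
    background_pairs = sum(len(set(r.reactions)) for r in background_reports)
    return ContingencyTable(a=a, b=cohort_pairs - a, c=c,
                            d=background_pairs - c)


def pair_count_frame(cohort_pts: Sequence[Iterable[str]],
                     background_pts: Sequence[Iterable[str]]) -> pd.DataFrame:
    """Vectorized per-PT cells from per-report PT collections.

    Returns a DataFrame indexed by PT with columns a, b, c, d; PTs appearing
    in neither group are absent.  Equivalent to calling
    :func:`build_contingency` per PT, but one pass over the data.
    """
    def tally(groups: Sequence[Iterable[str]]) -> tuple[pd.Series, int]:
        counts: dict[str, int] = {}
        pairs = 0
        for pts in groups:
            unique = set(pts)
            pairs += len(unique)
            for pt in unique:
                counts[pt] = counts.get(pt, 0) + 1
        return pd.Series(counts, dtype="int64"), pairs

    a, cohort_pairs = tally(cohort_pts)
    c, background_pairs = tally(background_pts)
    frame = pd.DataFrame({"a": a, "c": c}).fillna(0).astype("int64")
    frame["b"] = cohort_pairs - frame["a"]
    frame["d"] = background_pairs - frame["c"]
    return frame[["a", "b", "c", "d"]].sort_index()


# ---------------------------------------------------------------------------
# estimators


def compute_ror(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """(ror, lo, hi, se_ln_ror, flag); infinite with flag False on zero b/c."""
    if t.b == 0 or t.c == 0:
        return math.inf, math.nan, math.nan, math.nan, False
    if t.a == 0:
        return 0.0, math.nan, math.nan, math.nan, False
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) if t.d else math.nan
    lo = ror * math.exp(-Z95 * se)
    hi = ror * math.exp(Z95 * se)
    return ror, lo, hi, se, (lo >= 1.0) and (t.a >= 3)


def compute_prr_chi2(t: ContingencyTable
                     ) -> tuple[float, float, float, float, bool, bool]:
    """(prr, lo, hi, chi2, prr_flag, mhra_flag)."""
    chi2 = pearson_chi2(t)
    if t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return math.inf, math.nan, math.nan, chi2, False, False
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    if t.a == 0:
        return prr, math.nan, math.nan, chi2, False, False
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    lo = prr * math.exp(-Z95 * se)
    hi = prr * math.exp(Z95 * se)
    prr_flag = (t.a >= 3) and (lo >= 1.0) and (prr >= 2.0)
    mhra_flag = (t.a >= 3) and (prr > 2.0) and (chi2 >= 4.0)
    return prr, lo, hi, chi2, prr_flag, mhra_flag


def pearson_chi2(t: ContingencyTable) -> float:
    a, b, c, d = (float(t.a), float(t.b), float(t.c), float(t.d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return (a * d - b * c) ** 2 * n / denom


def compute_bcpnn(t: ContingencyTable,
                  priors: BcpnnPriors = DEFAULT_PRIORS
                  ) -> tuple[float, float, float, float, bool]:
    """(ic, e_ic, v_ic, ic_minus_2sd, flag).

    The priors keep every term finite even with zero cells; the observed IC
    itself is ±inf when a or a margin is zero.
    """
    a, n = float(t.a), float(t.n)
    m1, m2 = float(t.a + t.b), float(t.a + t.c)
    if a > 0 and m1 > 0 and m2 > 0:
        ic = math.log2(a * n / (m1 * m2))
    else:
        ic = -math.inf
    g = priors.gamma(t)
    e_ic = math.log2(
        (a + priors.gamma11) * (n + priors.alpha) * (n + priors.beta)
        / ((n + g) * (m1 + priors.alpha1) * (m2 + priors.beta1))
    )
    v_ic = (
        (n - a + g - priors.gamma11) / ((a + priors.gamma11) * (1 + n + g))
        + (n - m1 + priors.alpha - priors.alpha1)
        / ((m1 + priors.alpha1) * (1 + n + priors.alpha))
        + (n - m2 + priors.beta - priors.beta1)
        / ((m2 + priors.beta1) * (1 + n + priors.beta))
    ) / math.log(2) ** 2
    ic_minus_2sd = e_ic - 2.0 * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic_minus_2sd, ic_minus_2sd > 0.0


def compute_ebgm(t: ContingencyTable) -> tuple[float, float, float, bool]:
    """(ebgm, eb05, eb95, flag) for the simplified EBGM = aN/((a+c)(a+b))."""
    m1, m2 = t.a + t.b, t.a + t.c
    if m1 == 0 or m2 == 0:
        return math.nan, math.nan, math.nan, False
    ebgm = t.a * t.n / (m2 * m1)
    if t.degenerate:
        return ebgm, math.nan, math.nan, False
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    eb05 = ebgm * math.exp(-Z95 * se)
    eb95 = ebgm * math.exp(Z95 * se)
    return ebgm, eb05, eb95, eb05 >= 2.0


def score_table(pt: str, t: ContingencyTable,
                soc: Optional[str] = None,
                priors: BcpnnPriors = DEFAULT_PRIORS) -> SignalScores:
    s = SignalScores(pt=pt, soc=soc, a=t.a, table=t, degenerate=t.degenerate)
    s.ror, s.ror_lo, s.ror_hi, s.se_ln_ror, ror_flag = compute_ror(t)
    (s.prr, s.prr_lo, s.prr_hi, s.chi2,
     prr_flag, mhra_flag) = compute_prr_chi2(t)
    s.ic, s.e_ic, s.v_ic, s.ic_minus_2sd, bcpnn_flag = compute_bcpnn(t, priors)
    s.ebgm, s.eb05, s.eb95, mgps_flag = compute_ebgm(t)
    if t.degenerate or t.a + t.c == 0:
        ror_flag = prr_flag = mhra_flag = bcpnn_flag = mgps_flag = False
    s.flags = {
        "ror_signal": ror_flag,
        "prr_signal": prr_flag,
        "mhra_signal": mhra_flag,
        "bcpnn_signal": bcpnn_flag,
        "mgps_signal": mgps_flag,
    }
    return s


def score_all(cohort_reports: Sequence[CaseReport],
              background_reports: Sequence[CaseReport],
              pts: Optional[Sequence[str]] = None,
              meddra: Optional[MeddraMap] = None,
              priors: BcpnnPriors = DEFAULT_PRIORS) -> list[SignalScores]:
    """Score every requested PT observed at least once in the cohort.

    With ``pts=None``, all PTs reported in the cohort are scored.  Results
    are deterministically ordered by (a desc, pt asc).
    """
    frame = pair_count_frame(
        [r.reactions for r in cohort_reports],
        [r.reactions for r in background_reports],
    )
    if pts is not None:
        frame = frame.loc[frame.index.intersection(list(pts))]
    frame = frame[frame["a"] >= 1]
    scores = []
    for pt, row in frame.iterrows():
        t = ContingencyTable(int(row["a"]), int(row["b"]),
                             int(row["c"]), int(row["d"]))
        soc = meddra.soc_of(pt) if meddra is not None else None
        scores.append(score_table(str(pt), t, soc=soc, priors=priors))
    scores.sort(key=lambda s: (-s.a, s.pt))
    return scores


# ---------------------------------------------------------------------------
# ranking and export


def rank_frequency(scores: Sequence[SignalScores], k: int) -> pd.DataFrame:
    """Top-k ROR-positive PTs by report count a (ties alphabetical)."""
    positive = [s for s in scores if s.flags.get("ror_signal")]
    positive.sort(key=lambda s: (-s.a, s.pt))
    return signal_frame(positive[:k])


def rank_strength(scores: Sequence[SignalScores], k: int) -> pd.DataFrame:
    """Top-k ROR-positive PTs by ROR magnitude (ties by a desc, then PT)."""
    positive = [s for s in scores if s.flags.get("ror_signal")]
    positive.sort(key=lambda s: (-s.ror, -s.a, s.pt))
    return signal_frame(positive[:k])


def signal_frame(scores: Sequence[SignalScores]) -> pd.DataFrame:
    """Publication-style layout: PT, N, ROR (95%CI), PRR (X^2), IC-2SD, EBGM05."""
    rows = []
    for s in scores:
        rows.append({
            "PT": s.pt,
            "SOC": s.soc or "",
            "N": s.a,
            "ROR (95%CI)": f"{s.ror:.2f} ({s.ror_lo:.2f},{s.ror_hi:.2f})",
            "PRR (X^2)": f"{s.prr:.2f} ({s.chi2:.2f})",
            "IC-2SD": f"{s.ic_minus_2sd:.2f}",
            "EBGM05": f"{s.eb05:.2f}",
        })
    return pd.DataFrame(
        rows, columns=["PT", "SOC", "N", "ROR (95%CI)", "PRR (X^2)",
                       "IC-2SD", "EBGM05"])


def aggregate_soc(cohort_reports: Sequence[CaseReport],
                  background_reports: Sequence[CaseReport],
                  meddra: MeddraMap,
                  priors: BcpnnPriors = DEFAULT_PRIORS) -> list[SignalScores]:
    """SOC-level scores: a report counts once per SOC its PTs map to."""
    def socs(report: CaseReport) -> set[str]:
        return {meddra.soc_of(pt) or "Unmapped" for pt in report.reactions}

    frame = pair_count_frame(
        [socs(r) for r in cohort_reports],
        [socs(r) for r in background_reports],
    )
    frame = frame[frame["a"] >= 1]
    scores = []
    for soc, row in frame.iterrows():
        t = ContingencyTable(int(row["a"]), int(row["b"]),
                             int(row["c"]), int(row["d"]))
        scores.append(score_table(str(soc), t, soc=str(soc), priors=priors))
    scores.sort(key=lambda s: (-s.a, s.pt))
    return scores


# ---------------------------------------------------------------------------
# reconstruction of a 2x2 table from published row statistics


def reconstruct_from_stats(a: int,
                           ror: float,
                           ror_lo: float,
                           ror_hi: float,
                           prr: float,
                           chi2: Optional[float] = None,
                           eb05: Optional[float] = None) -> ContingencyTable:
    """Recover integer cells b, c, d from one published table row.

    Published disproportionality tables print a, ROR with its CI, PRR and
    (some of) χ²/EB05, but not the underlying cells.  Those statistics
    over-determine the three unknown cells: the CI fixes
    SE² = 1/a + 1/b + 1/c + 1/d, PRR together with ROR fixes b
    (b = a(PRR−1)/(ROR−PRR)), and χ² or EB05 fixes the scale of c.
    The cells are found by precision-weighted least squares on the log scale
    (each published value weighted by its printed rounding precision of
    ±0.005) followed by a local integer search.

    The remaining, unused statistics of the row can then be predicted from
    the reconstructed table as a consistency check.
    """
    if ror <= prr:
        raise ValueError("requires ROR > PRR (a background-dominated database)")
    se = (math.log(ror_hi / ror) + math.log(ror / ror_lo)) / (2 * Z95)
    b0 = a * (prr - 1.0) / (ror - prr)
    s2 = se ** 2 - 1 / a - 1 / b0
    c0 = (1 + a / (ror * b0)) / s2 if s2 > 0 else 50 * b0
    d0 = ror * b0 * c0 / a

    observed = {"ror": ror, "prr": prr}
    if chi2 is not None:
        observed["chi2"] = chi2
    if eb05 is not None:
        observed["eb05"] = eb05
    weights = {k: v / 0.005 for k, v in observed.items()}
    w_se = 2 * Z95 * se / (0.005 / ror_hi + 0.005 / ror_lo)

    def stats_of(b: np.ndarray, c: np.ndarray, d: np.ndarray) -> dict[str, np.ndarray]:
        af = float(a)
        n = af + b + c + d
        se_t = np.sqrt(1 / af + 1 / b + 1 / c + 1 / d)
        ebgm = af * n / ((af + c) * (af + b))
        return {
            "ror": af * d / (b * c),
            "prr": (af / (af + b)) / (c / (c + d)),
            "chi2": (af * d - b * c) ** 2 * n / ((af + b) * (c + d) * (af + c) * (b + d)),
            "eb05": ebgm * np.exp(-Z95 * se_t),
            "se": se_t,
        }

    def residuals(x: np.ndarray) -> list[float]:
        st = stats_of(*np.exp(x[:, None]))
        out = [float(np.log(st[k][0] / observed[k])) * weights[k] for k in observed]
        out.append((float(st["se"][0]) - se) / se * w_se)
        return out

    sol = least_squares(residuals, np.log([b0, c0, d0]),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    b1, c1, d1 = np.exp(sol.x)

    best: Optional[tuple[float, int, int, int]] = None
    for b in range(max(1, round(b1) - 3), round(b1) + 4):
        for c in range(max(1, round(c1) - 4), round(c1) + 5):
            d_center = d1 * (b * c) / (b1 * c1)
            ds = np.arange(max(1.0, math.floor(d_center) - 60),
                           math.floor(d_center) + 61)
            st = stats_of(np.full_like(ds, float(b)),
                          np.full_like(ds, float(c)), ds)
            score = np.zeros(len(ds))
            for k in observed:
                score += (np.log(st[k] / observed[k]) * weights[k]) ** 2
            score += ((st["se"] - se) / se * w_se) ** 2
            i = int(np.argmin(score))
            if best is None or score[i] < best[0]:
                best = (float(score[i]), b, c, int(ds[i]))
    assert best is not None
    _, b, c, d = best
    return ContingencyTable(a=a, b=b, c=c, d=d)
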