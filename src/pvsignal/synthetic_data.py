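"""Synthetic spontaneous-reporting databases with known ground truth.

Generates FAERS-dialect quarterly extracts in which drug–event dependence,
demographics, onset times, outcome mix, duplicate chains and deletion lists
are all planted with known laws, so that every pipeline stage can be tested
end to end without downloading anything.

Generative law (per report)
---------------------------
* cohort membership ~ Bernoulli(cohort_fraction); cohort reports carry the
  target drug as primary suspect with a qualifying indication, background
  reports draw their primary suspect from ``drug_vocab``;
* the number of reaction draws K is zero-truncated Poisson(mean_pts); the K
  draws are taken with replacement from the PT vocabulary and de-duplicated,
  so a PT with normalized weight w is included with probability
  E[1 − (1−w)^K] — the closed form used by :func:`expected_table`;
* for a report whose primary suspect is the drug of a planted (drug, pt, rr)
  pair, that PT's weight is multiplied by rr before renormalization, which
  tilts reporting toward the pair at approximately the requested relative
  reporting ratio;
* duplicate chains share a CASEID across 2–3 versions with non-decreasing
  FDA receipt dates and increasing PRIMARYIDs (occasionally an exact date
  tie, exercising the PRIMARYID tie-break); deletion lists name a random
  subset of final CASEIDs.

Demographic defaults emulate reporting patterns of checkpoint-inhibitor
safety data in a gynaecologic-oncology population: mostly female, age
centred in the 45–65 stratum, weight mostly unreported, onset log-normal
with its mode in the 3–6 month bucket, outcome mix dominated by
"other"/hospitalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import poisson

from .disproportionality import ContingencyTable

TARGET_DRUG = "pembrolizumab"

DEFAULT_DRUG_VOCAB = {
    "cisplatin": 0.16, "paclitaxel": 0.16, "carboplatin": 0.14,
    "bevacizumab": 0.12, "nivolumab": 0.08, "atezolizumab": 0.06,
    "topotecan": 0.06, "metformin": 0.08, "lisinopril": 0.07,
    "omeprazole": 0.07,
}

# background weights over the bundled PT vocabulary: common general terms
# heavier, signal-table terms rarer (they are the ones that get planted)
_COMMON = ("nausea", "vomiting", "diarrhoea", "fatigue", "pyrexia", "headache",
           "rash", "pruritus", "dizziness", "dyspnoea", "cough", "constipation",
           "abdominal pain", "decreased appetite", "arthralgia", "myalgia",
           "insomnia", "hypertension", "hyponatraemia", "pneumonia",
           "urinary tract infection", "sepsis", "dehydration", "back pain",
           "oedema peripheral", "drug ineffective", "alopecia", "stomatitis",
           "thrombocytopenia", "asthenia")
_RARE = ("malignant neoplasm progression", "product use in unapproved indication",
         "anemia", "neutropenia", "adverse event", "neuropathy peripheral",
         "inappropriate schedule of product administration", "skin disorder",
         "neutrophil count decreased", "myelosuppression", "febrile neutropenia",
         "hypothyroidism", "drug eruption", "immune-mediated enterocolitis",
         "female genital tract fistula", "renal impairment",
         "intestinal perforation", "platelet count decreased",
         "urogenital fistula", "colitis", "immune-mediated endocrinopathy",
         "hepatic function abnormal", "transfusion", "proteinuria",
         "immune-mediated hepatic disorder", "immune-mediated hypothyroidism",
         "erythema multiforme",
         "eastern cooperative oncology group performance status worsened",
         "cytokine release syndrome", "cervix carcinoma recurrent",
         "immune-mediated cholangitis", "ureteral stent insertion",
         "immune-mediated adrenal insufficiency", "immune-mediated hypophysitis",
         "immune-mediated encephalitis", "gastroenteritis radiation",
         "enanthema", "duodenal perforation", "cortisol decreased",
         "packed red blood cell transfusion", "immune-mediated hepatitis",
         "lymphadenopathy", "pyelonephritis", "uterine haemorrhage",
         "gastrointestinal perforation")


def default_pt_vocab() -> dict[str, float]:
    vocab = {pt: 3.0 for pt in _COMMON}
    vocab.update({pt: 0.35 for pt in _RARE})
    return vocab


def uniform_pt_vocab(n: int, prefix: str = "background reaction") -> dict[str, float]:
    """n equally-weighted synthetic PTs, for null-calibration studies."""
    return {f"{prefix} {i:03d}": 1.0 for i in range(n)}


DEFAULT_PLANTED = [
    (TARGET_DRUG, "malignant neoplasm progression", 30.0),
    (TARGET_DRUG, "product use in unapproved indication", 9.0),
    (TARGET_DRUG, "neutropenia", 7.5),
    (TARGET_DRUG, "immune-mediated enterocolitis", 20.0),
    (TARGET_DRUG, "urogenital fistula", 25.0),
    (TARGET_DRUG, "immune-mediated endocrinopathy", 18.0),
]

DEFAULT_COUNTRIES = {"JP": 0.5356, "US": 0.2353, "KR": 0.0588, "CN": 0.0309,
                     "FR": 0.0201, "DE": 0.0193, "GB": 0.05, "IT": 0.05}
DEFAULT_OCCUPATIONS = {"MD": 0.636, "OT": 0.199, "PH": 0.15, "CN": 0.015}
DEFAULT_OUTCOMES = {"OT": 0.528, "HO": 0.27, "DE": 0.1025, "": 0.0606,
                    "LT": 0.0277, "DS": 0.0112}


class SyntheticConfig(BaseModel):
    """Generative parameters; identical config ⇒ byte-identical output."""

    model_config = ConfigDict(extra="forbid")

    n_reports: int = 2000
    quarters: list[str] = Field(
        default_factory=lambda: ["23Q1", "23Q2", "23Q3", "23Q4"])
    target_drug: str = TARGET_DRUG
    indication_pts: list[str] = Field(
        default_factory=lambda: ["cervix carcinoma"])
    drug_vocab: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DRUG_VOCAB))
    pt_vocab: dict[str, float] = Field(default_factory=default_pt_vocab)
    planted_pairs: list[tuple[str, str, float]] = Field(
        default_factory=lambda: list(DEFAULT_PLANTED))
    cohort_fraction: float = 0.15
    mean_pts_per_report: float = 3.0
    age_mean: float = 58.0
    age_sd: float = 13.0
    age_missing: float = 0.08
    weight_mean: float = 62.0   # median, kg (log-normal law)
    weight_sd: float = 20.0     # sets the log-scale sd via the CV weight_sd/weight_mean
    weight_missing: float = 0.35
    onset_meanlog: float = math.log(130.0)
    onset_sdlog: float = 0.6
    onset_missing: float = 0.42
    country_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COUNTRIES))
    occupation_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OCCUPATIONS))
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES))
    duplicate_rate: float = 0.12
    deletion_rate: float = 0.02
    concomitant_target_rate: float = 0.03
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticConfig":
        for name in ("cohort_fraction", "age_missing", "weight_missing",
                     "onset_missing", "duplicate_rate", "deletion_rate",
                     "concomitant_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for drug, pt, rr in self.planted_pairs:
            if pt not in self.pt_vocab:
                raise ValueError(f"planted PT {pt!r} not in pt_vocab")
            if rr <= 0:
                raise ValueError(f"planted RR must be > 0 for {(drug, pt)}")
        total = sum(self.pt_vocab.values())
        for drug, pt, rr in self.planted_pairs:
            if rr * self.pt_vocab[pt] / total >= 1.0:
                raise ValueError(
                    f"infeasible RR for pair {(drug, pt)}: tilted inclusion "
                    "probability would exceed 1")
        return self


@dataclass
class GroundTruth:
    """What the generator actually planted, for exact recounts in tests."""

    # realized post-dedup cells per planted pair
    tables: dict[tuple[str, str], ContingencyTable]
    # one row per generated case: caseid, kept primaryid, flags
    reports: pd.DataFrame
    expected: dict[tuple[str, str], ContingencyTable] = field(default_factory=dict)

    def sidecar_frame(self) -> pd.DataFrame:
        return self.reports


# ---------------------------------------------------------------------------
# sampling primitives


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    k = rng.poisson(lam, size)
    while (zero := k == 0).any():
        k[zero] = rng.poisson(lam, int(zero.sum()))
    return k


def _categorical(rng: np.random.Generator, probs: dict[str, float],
                 size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=size, p=p)]


def _tilted_weights(config: SyntheticConfig, ps_drug: str) -> np.ndarray:
    pts = list(config.pt_vocab)
    w = np.array([config.pt_vocab[pt] for pt in pts], dtype=float)
    for drug, pt, rr in config.planted_pairs:
        if drug == ps_drug:
            w[pts.index(pt)] *= rr
    return w / w.sum()


def sample_report_pts(config: SyntheticConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Fast path: (is_cohort, ps_drug, reaction PT lists) for n_reports.

    This is the exact reaction law used by :func:`generate`; scoring studies
    that do not need files or demographics can run on it directly.
    """
    n = config.n_reports
    is_cohort = rng.random(n) < config.cohort_fraction
    ps_drug = np.empty(n, dtype=object)
    ps_drug[is_cohort] = config.target_drug
    n_bg = int((~is_cohort).sum())
    ps_drug[~is_cohort] = _categorical(rng, config.drug_vocab, n_bg)

    pts = np.array(list(config.pt_vocab), dtype=object)
    k = _truncated_poisson(rng, config.mean_pts_per_report, n)
    reactions: list[list[str]] = [[] for _ in range(n)]
    for drug in sorted({config.target_drug, *config.drug_vocab}):
        mask = ps_drug == drug
        if not mask.any():
            continue
        weights = _tilted_weights(config, drug)
        idx = np.flatnonzero(mask)
        draws = rng.choice(len(pts), size=int(k[idx].sum()), p=weights)
        offsets = np.concatenate([[0], np.cumsum(k[idx])])
        for j, report_i in enumerate(idx):
            chosen = draws[offsets[j]:offsets[j + 1]]
            reactions[report_i] = sorted(set(pts[chosen]))
    return is_cohort, ps_drug, reactions


# ---------------------------------------------------------------------------
# expected contingency cells under the generative law


def _inclusion_prob(w: float, lam: float) -> float:
    """P(PT included) = E[1-(1-w)^K] for zero-truncated Poisson K."""
    kmax = int(poisson.isf(1e-12, lam)) + 1
    ks = np.arange(1, kmax + 1)
    pk = poisson.pmf(ks, lam) / (1.0 - math.exp(-lam))
    return float(np.sum(pk * (1.0 - (1.0 - w) ** ks)))


def expected_table(config: SyntheticConfig,
                   pair: tuple[str, str]) -> ContingencyTable:
    """Closed-form expected a, b, c, d for one (drug, pt) pair.

    Rows of the table split reports by primary-suspect drug.  Cells are
    rounded expectations; they anchor tolerance checks against realized
    counts, not exact equalities.
    """
    drug, pt = pair
    if pt not in config.pt_vocab:
        raise KeyError(f"unknown PT {pt!r}")
    known_drugs = {config.target_drug, *config.drug_vocab}
    if drug not in known_drugs:
        raise KeyError(f"unknown drug {drug!r}")
    lam = config.mean_pts_per_report
    pts = list(config.pt_vocab)
    pt_i = pts.index(pt)

    def group_stats(ps: str) -> tuple[float, float]:
        w = _tilted_weights(config, ps)
        incl = _inclusion_prob(float(w[pt_i]), lam)
        mu = sum(_inclusion_prob(float(wy), lam) for wy in w)
        return incl, mu

    # deletion-listed cases drop out before counting, independently of content
    n = config.n_reports * (1.0 - config.deletion_rate)
    drug_share = {config.target_drug: config.cohort_fraction}
    bg_total = sum(config.drug_vocab.values())
    for name, p in config.drug_vocab.items():
        drug_share[name] = (1.0 - config.cohort_fraction) * p / bg_total

    n_row = n * drug_share[drug]
    incl, mu = group_stats(drug)
    ea = n_row * incl
    eb = n_row * mu - ea
    ec = ed = 0.0
    for other, share in drug_share.items():
        if other == drug:
            continue
        incl_o, mu_o = group_stats(other)
        ec += n * share * incl_o
        ed += n * share * (mu_o - incl_o)
    return ContingencyTable(a=round(ea), b=round(eb), c=round(ec), d=round(ed))


# ---------------------------------------------------------------------------
# full generation


def _quarter_dates(label: str) -> tuple[date, date]:
    year = 2000 + int(label[:2])
    q = int(label[-1])
    start = date(year, 3 * q - 2, 1)
    end = date(year + (q == 4), 1 if q == 4 else 3 * q + 1, 1) - timedelta(days=1)
    return start, end


def _fmt(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate(config: SyntheticConfig
             ) -> tuple[list["RawQuarter"], GroundTruth]:
    """Generate quarterly extracts plus ground truth.

    Same config (including seed) produces identical output.
    """
    from .faers_io import RawQuarter  # local to avoid cycle at import time

    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    is_cohort, ps_drug, reactions = sample_report_pts(config, rng)

    quarters = {q: RawQuarter(quarter_id=q) for q in config.quarters}
    q_of = [config.quarters[i] for i in rng.integers(0, len(config.quarters), n)]

    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95)
    age_missing = rng.random(n) < config.age_missing
    age_unit_roll = rng.random(n)
    weights = np.clip(rng.lognormal(math.log(config.weight_mean),
                                    config.weight_sd / config.weight_mean, n),
                      35, 170)
    weight_missing = rng.random(n) < config.weight_missing
    weight_unit_roll = rng.random(n)
    sexes = np.where(is_cohort, "F",
                     np.where(rng.random(n) < 0.55, "F", "M"))
    countries = _categorical(rng, config.country_probs, n)
    occupations = _categorical(rng, config.occupation_probs, n)
    outcomes = _categorical(rng, config.outcome_probs, n)
    extra_hosp = (outcomes == "DE") & (rng.random(n) < 0.1)
    onset = np.rint(rng.lognormal(config.onset_meanlog, config.onset_sdlog, n)
                    ).astype(int).clip(0, 2000)
    onset_documented = rng.random(n) < (1.0 - config.onset_missing)
    n_versions = np.where(rng.random(n) < config.duplicate_rate,
                          rng.integers(2, 4, n), 1)
    tie_roll = rng.random(n)
    deleted = rng.random(n) < config.deletion_rate
    n_conc = rng.integers(0, 3, n)
    conc_target = (~is_cohort) & (rng.random(n) < config.concomitant_target_rate)
    bg_indication = _categorical(
        rng, {"hypertension": 0.4, "insomnia": 0.3, "back pain": 0.3}, n)

    report_rows = []
    for i in range(n):
        caseid = 3_000_000 + i
        quarter = quarters[q_of[i]]
        qstart, qend = _quarter_dates(q_of[i])
        span = (qend - qstart).days
        final_fda = qstart + timedelta(days=int(rng.integers(0, span + 1)))
        versions = int(n_versions[i])
        fda_dates = [final_fda]
        for v in range(versions - 1):
            if v == 0 and tie_roll[i] < 0.3:
                fda_dates.append(final_fda)  # date tie; PRIMARYID breaks it
            else:
                fda_dates.append(fda_dates[-1] - timedelta(
                    days=int(rng.integers(7, 90))))
        fda_dates = fda_dates[::-1]  # oldest first; final report is last
        start_dt = final_fda - timedelta(days=int(onset[i]) + 30)
        event_dt = start_dt + timedelta(days=int(onset[i]))

        for v, fda in enumerate(fda_dates):
            primaryid = caseid * 10 + v
            is_final = v == len(fda_dates) - 1
            quarter.demo_rows.append({
                "primaryid": str(primaryid),
                "caseid": str(caseid),
                "fda_dt": _fmt(fda),
                "event_dt": _fmt(event_dt) if onset_documented[i] else "",
                "age": ("" if age_missing[i] else _age_field(
                    ages[i], age_unit_roll[i])[0]),
                "age_cod": ("" if age_missing[i] else _age_field(
                    ages[i], age_unit_roll[i])[1]),
                "wt": ("" if weight_missing[i] else _weight_field(
                    weights[i], weight_unit_roll[i])[0]),
                "wt_cod": ("" if weight_missing[i] else _weight_field(
                    weights[i], weight_unit_roll[i])[1]),
                "sex": str(sexes[i]),
                "occr_country": str(countries[i]),
                "occp_cod": str(occupations[i]),
            })
            drug_rows = [(1, str(ps_drug[i]), "PS")]
            extra = ["cisplatin", "paclitaxel", "omeprazole", "metformin"]
            for j in range(int(n_conc[i])):
                drug_rows.append((2 + j, extra[j], "C"))
            if conc_target[i]:
                drug_rows.append((len(drug_rows) + 1, config.target_drug, "C"))
            for seq, name, role in drug_rows:
                quarter.drug_rows.append({
                    "primaryid": str(primaryid), "drug_seq": str(seq),
                    "drugname": name, "role_cod": role,
                })
            indication = (
                config.indication_pts[i % len(config.indication_pts)]
                if is_cohort[i] else str(bg_indication[i]))
            quarter.indi_rows.append({
                "primaryid": str(primaryid), "indi_drug_seq": "1",
                "indi_pt": indication,
            })
            for pt in reactions[i]:
                quarter.reac_rows.append({"primaryid": str(primaryid), "pt": pt})
            if outcomes[i]:
                quarter.outc_rows.append({
                    "primaryid": str(primaryid), "outc_cod": str(outcomes[i])})
            if extra_hosp[i]:
                quarter.outc_rows.append({
                    "primaryid": str(primaryid), "outc_cod": "HO"})
            if onset_documented[i]:
                quarter.ther_rows.append({
                    "primaryid": str(primaryid), "dsg_drug_seq": "1",
                    "start_dt": _fmt(start_dt),
                })
            if is_final:
                report_rows.append({
                    "caseid": caseid,
                    "primaryid": primaryid,
                    "quarter": q_of[i],
                    "is_cohort": bool(is_cohort[i]),
                    "ps_drug": str(ps_drug[i]),
                    "n_versions": versions,
                    "deleted": bool(deleted[i]),
                    "irae": any(pt.startswith("immune-mediated")
                                for pt in reactions[i]),
                    "onset_days": int(onset[i]) if onset_documented[i] else -1,
                    "outcome": str(outcomes[i]),
                })
        if deleted[i]:
            quarter.deleted_caseids.append(caseid)

    truth_reports = pd.DataFrame(report_rows)
    surviving = truth_reports[~truth_reports["deleted"]]
    keep_idx = surviving["primaryid"].to_numpy()
    idx_of = {int(pid): int(pid) // 10 - 3_000_000 for pid in keep_idx}

    tables = {}
    for drug, pt, _rr in config.planted_pairs:
        tables[(drug, pt)] = _recount(config, drug, pt,
                                      [idx_of[int(p)] for p in keep_idx],
                                      is_cohort, ps_drug, reactions)
    expected = {(drug, pt): expected_table(config, (drug, pt))
                for drug, pt, _rr in config.planted_pairs}
    truth = GroundTruth(tables=tables, reports=truth_reports, expected=expected)
    return [quarters[q] for q in config.quarters], truth


def _age_field(age: float, roll: float) -> tuple[str, str]:
    if roll < 0.9:
        return str(int(round(age))), "YR"
    if roll < 0.95:
        return str(int(round(age * 12))), "MON"
    return str(int(round(age / 10))), "DEC"


def _weight_field(weight: float, roll: float) -> tuple[str, str]:
    if roll < 0.85:
        return f"{weight:.1f}", "KG"
    return f"{weight / 0.453592:.1f}", "LBS"


def _recount(config: SyntheticConfig, drug: str, pt: str,
             kept_indices: Sequence[int], is_cohort: np.ndarray,
             ps_drug: np.ndarray, reactions: list[list[str]]) -> ContingencyTable:
    a = b = c = d = 0
    for i in kept_indices:
        row_drug = ps_drug[i] == drug
        n_pts = len(reactions[i])
        has_pt = pt in reactions[i]
        if row_drug:
            a += has_pt
            b += n_pts - has_pt
        else:
            c += has_pt
            d += n_pts - has_pt
    return ContingencyTable(a=a, b=b, c=c, d=d)


def simulate_irae_design(n: int,
                         beta: dict[str, float],
                         intercept: float = -1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Draw a cohort directly from the logistic irAE model.

    ``beta`` maps covariate names (age>=65, weight50-100, weight>100,
    offlabel_no) to log-odds; unlisted covariates get 0.  Returns a frame
    with the binary covariates and outcome, for parameter-recovery studies.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "age>=65": (rng.random(n) < 0.40).astype(float),
        "weight50-100": np.zeros(n),
        "weight>100": np.zeros(n),
        "offlabel_no": (rng.random(n) < 0.6).astype(float),
    })
    wcat = rng.choice(3, size=n, p=[0.30, 0.45, 0.25])
    X.loc[wcat == 1, "weight50-100"] = 1.0
    X.loc[wcat == 2, "weight>100"] = 1.0
    eta = intercept + sum(
        beta.get(col, 0.0) * X[col].to_numpy() for col in X.columns)
    X["irae"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X
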