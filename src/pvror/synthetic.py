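"""Synthetic FAERS-like data with known ground truth.

Generates the five quarterly ASCII tables for a configurable number of
cases so the whole pipeline — parsing, deduplication, cohort
construction, descriptives and signal detection — can be exercised and
validated without a FAERS download.  The generator emulates:

* report versioning: a configurable fraction of cases gets an extra
  DEMO row that the three deduplication rules must remove (an exact
  copy, a superseded lower ``primary_id``, or the same ``primary_id``
  with an earlier receipt date);
* demographics with FAERS unit codes and per-field missingness;
* one primary-suspect drug per case (the target drug with probability
  ``target_share``, else a comparator antiviral/COVID drug), with
  free-text names, and dose fields for the target drug;
* COVID-19 indications drawn from the 18-term narrow SMQ, plus a
  fraction of non-COVID cases the cohort step must drop;
* reaction PTs drawn per-term from a toy MedDRA-like vocabulary
  (~60 PTs across 18 system organ classes), with *planted* odds
  multipliers θ on the target group so the true reporting odds ratio
  is analytically known;
* uninformative reaction terms ("Product use issue", ...) injected so
  the event filter has work to do;
* seriousness outcome codes and label-relative dosing.

Events are independent per-report Bernoulli draws: in the comparator
group PT *j* occurs with its baseline probability ``p_j``; in the
target group with the θ-shifted probability
``θ·p_j / (1 − p_j + θ·p_j)``, so the per-report odds ratio between
groups is exactly θ.  Under the report-count denominator the ROR is a
consistent estimator of θ.

All randomness flows from ``config.seed`` through one NumPy
``Generator``; the same config yields byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as faers_io
from .cohort import COVID_SMQ_TERMS, SafetyCase
from .records import (
    DrugRecord,
    IndicationRecord,
    OutcomeRecord,
    RawReport,
    ReactionRecord,
    TableKind,
)

#: Toy MedDRA-like vocabulary: (preferred term, system organ class,
#: baseline per-report reporting probability).  The terms are real PT
#: names; the hierarchy placement follows common MedDRA usage but the
#: list is a stand-in for the licensed dictionary, not an excerpt.
DEFAULT_VOCABULARY: Tuple[Tuple[str, str, float], ...] = (
    # Skin and subcutaneous tissue disorders
    ("Rash", "Skin and subcutaneous tissue disorders", 0.050),
    ("Urticaria", "Skin and subcutaneous tissue disorders", 0.015),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.012),
    ("Drug eruption", "Skin and subcutaneous tissue disorders", 0.002),
    ("Toxic skin eruption", "Skin and subcutaneous tissue disorders", 0.001),
    # Gastrointestinal disorders
    ("Diarrhoea", "Gastrointestinal disorders", 0.060),
    ("Nausea", "Gastrointestinal disorders", 0.045),
    ("Vomiting", "Gastrointestinal disorders", 0.035),
    ("Abdominal pain", "Gastrointestinal disorders", 0.020),
    ("Dysphagia", "Gastrointestinal disorders", 0.004),
    ("Constipation", "Gastrointestinal disorders", 0.008),
    ("Melaena", "Gastrointestinal disorders", 0.002),
    ("Faeces soft", "Gastrointestinal disorders", 0.002),
    ("Haematochezia", "Gastrointestinal disorders", 0.002),
    # Infections and infestations
    ("Pneumonia", "Infections and infestations", 0.015),
    ("Pneumonia aspiration", "Infections and infestations", 0.002),
    ("Urinary tract infection", "Infections and infestations", 0.006),
    # Respiratory, thoracic and mediastinal disorders
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.030),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.020),
    ("Respiratory failure",
     "Respiratory, thoracic and mediastinal disorders", 0.006),
    ("Sputum retention",
     "Respiratory, thoracic and mediastinal disorders", 0.001),
    ("Asphyxia", "Respiratory, thoracic and mediastinal disorders", 0.001),
    # Nervous system disorders
    ("Dizziness", "Nervous system disorders", 0.040),
    ("Headache", "Nervous system disorders", 0.035),
    ("Seizure", "Nervous system disorders", 0.003),
    ("Cerebral infarction", "Nervous system disorders", 0.002),
    ("Altered state of consciousness", "Nervous system disorders", 0.002),
    # Psychiatric disorders
    ("Insomnia", "Psychiatric disorders", 0.010),
    ("Anxiety", "Psychiatric disorders", 0.008),
    ("Hallucination, visual", "Psychiatric disorders", 0.001),
    ("Abnormal behaviour", "Psychiatric disorders", 0.001),
    # Renal and urinary disorders
    ("Acute kidney injury", "Renal and urinary disorders", 0.008),
    ("Urinary retention", "Renal and urinary disorders", 0.002),
    ("Haematuria", "Renal and urinary disorders", 0.002),
    # Metabolism and nutrition disorders
    ("Decreased appetite", "Metabolism and nutrition disorders", 0.012),
    ("Dehydration", "Metabolism and nutrition disorders", 0.006),
    ("Marasmus", "Metabolism and nutrition disorders", 0.0005),
    # Cardiac disorders
    ("Atrial fibrillation", "Cardiac disorders", 0.004),
    ("Myocardial infarction", "Cardiac disorders", 0.003),
    ("Cardiac failure", "Cardiac disorders", 0.003),
    ("Cardiac failure chronic", "Cardiac disorders", 0.001),
    # Ear and labyrinth disorders
    ("Vertigo", "Ear and labyrinth disorders", 0.004),
    ("Tinnitus", "Ear and labyrinth disorders", 0.002),
    ("Deafness unilateral", "Ear and labyrinth disorders", 0.0005),
    # Hepatobiliary disorders
    ("Hepatic function abnormal", "Hepatobiliary disorders", 0.005),
    ("Hepatotoxicity", "Hepatobiliary disorders", 0.001),
    # Vascular disorders
    ("Hypertension", "Vascular disorders", 0.008),
    ("Hypotension", "Vascular disorders", 0.006),
    ("Hypertensive crisis", "Vascular disorders", 0.001),
    # Blood and lymphatic system disorders
    ("Anaemia", "Blood and lymphatic system disorders", 0.008),
    ("Thrombocytopenia", "Blood and lymphatic system disorders", 0.004),
    ("Neutropenia", "Blood and lymphatic system disorders", 0.002),
    # General disorders and administration site conditions
    ("Fatigue",
     "General disorders and administration site conditions", 0.030),
    ("Pyrexia", "General disorders and administration site conditions",
     0.025),
    ("Malaise", "General disorders and administration site conditions",
     0.015),
    ("Chest pain", "General disorders and administration site conditions",
     0.008),
    ("Oedema peripheral",
     "General disorders and administration site conditions", 0.005),
    # Immune system disorders
    ("Drug hypersensitivity", "Immune system disorders", 0.004),
    ("Anaphylactic reaction", "Immune system disorders", 0.001),
    # Eye disorders
    ("Vision blurred", "Eye disorders", 0.003),
    ("Conjunctivitis", "Eye disorders", 0.002),
    # Musculoskeletal and connective tissue disorders
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.008),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.008),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.005),
    # Investigations
    ("Alanine aminotransferase increased", "Investigations", 0.005),
    ("Blood creatinine increased", "Investigations", 0.003),
)

#: PT -> SOC mapping for the toy vocabulary.
def toy_pt_to_soc(
        vocabulary: Sequence[Tuple[str, str, float]] = DEFAULT_VOCABULARY,
) -> Dict[str, str]:
    return {pt: soc for pt, soc, _ in vocabulary}


TARGET_DRUG_NAMES = ("MOLNUPIRAVIR", "LAGEVRIO",
                     "LAGEVRIO (MOLNUPIRAVIR) 200MG")
COMPARATOR_DRUG_NAMES = (
    "REMDESIVIR", "VEKLURY", "FAVIPIRAVIR", "RIBAVIRIN", "AZVUDINE",
    "NIRMATRELVIR AND RITONAVIR", "PAXLOVID", "DEXAMETHASONE",
    "TOCILIZUMAB", "BARICITINIB", "CASIRIVIMAB AND IMDEVIMAB",
    "HYDROXYCHLOROQUINE SULFATE", "AZITHROMYCIN", "ENOXAPARIN SODIUM",
)
CONCOMITANT_DRUG_NAMES = ("PARACETAMOL", "IBUPROFEN", "ASPIRIN",
                          "OMEPRAZOLE", "AMLODIPINE")
NON_COVID_INDICATIONS = ("Influenza", "Hypertension", "Diabetes mellitus",
                         "Pain", "Depression")
EXCLUDED_EVENT_TERMS = ("Product use issue", "No adverse event",
                        "Wrong technique in product usage process",
                        "COVID-19")

# Indication weights concentrate on the common SMQ terms, with every
# term having some mass so covid_indication_ids is exercised fully.
_SMQ_TERMS_ORDERED = tuple(sorted(COVID_SMQ_TERMS))
_COMMON_INDICATIONS = {
    "COVID-19": 0.50,
    "COVID-19 treatment": 0.16,
    "COVID-19 pneumonia": 0.10,
    "SARS-CoV-2 test positive": 0.06,
    "COVID-19 prophylaxis": 0.04,
    "COVID-19 immunization": 0.03,
}
_REST = (1.0 - sum(_COMMON_INDICATIONS.values())) / (
    len(_SMQ_TERMS_ORDERED) - len(_COMMON_INDICATIONS))
INDICATION_WEIGHTS = tuple(
    _COMMON_INDICATIONS.get(t, _REST) for t in _SMQ_TERMS_ORDERED)


def planted_event_probability(p: float, theta: float) -> float:
    """Target-group event probability giving a per-report odds ratio θ
    against a comparator baseline probability ``p``."""
    return theta * p / (1.0 - p + theta * p)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic FAERS generator.

    The default sizes and category frequencies are modelled on the
    COVID-19 cohort observed in FAERS 2020–2022 (target share ≈2%,
    comparator-dominated demographics), scaled down to a number of
    cases that keeps generation fast.
    """

    n_cases: int = 10_000
    target_share: float = 0.02
    non_covid_rate: float = 0.10
    duplicate_version_rate: float = 0.05
    #: probabilities over the age bands <18, 18–44, 45–64, ≥65, Unknown
    age_probs: Tuple[float, ...] = (0.012, 0.128, 0.243, 0.274, 0.343)
    #: probabilities for F, M, missing
    sex_probs: Tuple[float, ...] = (0.520, 0.390, 0.090)
    #: probabilities for MD, PH, OT, CN, LW, missing
    occupation_probs: Tuple[float, ...] = (0.14, 0.06, 0.07, 0.54, 0.01,
                                           0.18)
    #: probabilities for US, JP, other named country, missing
    country_probs: Tuple[float, ...] = (0.687, 0.024, 0.214, 0.075)
    #: independent per-code probabilities for DE, LT, HO, DS, RI, CA, OT
    outcome_probs: Tuple[float, ...] = (0.07, 0.034, 0.20, 0.008, 0.009,
                                        0.001, 0.35)
    #: target-drug dose pattern: per label, below, above, missing
    dosage_probs: Tuple[float, ...] = (0.632, 0.088, 0.014, 0.266)
    excluded_event_rate: float = 0.05
    concomitant_rate: float = 0.30
    vocabulary: Tuple[Tuple[str, str, float], ...] = DEFAULT_VOCABULARY
    planted_effects: Mapping[str, float] = field(
        default_factory=lambda: {"Drug eruption": 20.0, "Dysphagia": 5.0,
                                 "Diarrhoea": 2.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not self.vocabulary:
            raise ValueError("vocabulary must be nonempty")
        for name in ("target_share", "non_covid_rate",
                     "duplicate_version_rate", "excluded_event_rate",
                     "concomitant_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for name in ("age_probs", "sex_probs", "occupation_probs",
                     "country_probs", "dosage_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
        if any(not 0.0 <= p <= 1.0 for p in self.outcome_probs):
            raise ValueError("outcome_probs must lie in [0, 1]")
        vocab_pts = {pt for pt, _, _ in self.vocabulary}
        for pt, _, p in self.vocabulary:
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline probability of {pt!r} "
                                 "must lie in (0, 1)")
            if pt in set(EXCLUDED_EVENT_TERMS):
                raise ValueError(f"{pt!r} is an excluded reaction term")
        for pt, theta in self.planted_effects.items():
            if pt not in vocab_pts:
                raise ValueError(f"planted effect on unknown PT {pt!r}")
            if theta <= 0:
                raise ValueError(f"planted θ for {pt!r} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact bookkeeping of what the generator planted.

    Counts refer to the deduplicated COVID-19 cohort: ``pt_counts``
    maps each PT to its (target, comparator) unique report counts.
    """

    seed: int
    n_target: int
    n_comparator: int
    target_pairs: int
    comparator_pairs: int
    pt_counts: Dict[str, Tuple[int, int]]
    planted_effects: Dict[str, float]

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "seed": self.seed,
            "n_target": self.n_target,
            "n_comparator": self.n_comparator,
            "target_pairs": self.target_pairs,
            "comparator_pairs": self.comparator_pairs,
            "pt_counts": {pt: list(v) for pt, v in self.pt_counts.items()},
            "planted_effects": dict(self.planted_effects),
        }, indent=1, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            seed=data["seed"],
            n_target=data["n_target"],
            n_comparator=data["n_comparator"],
            target_pairs=data["target_pairs"],
            comparator_pairs=data["comparator_pairs"],
            pt_counts={pt: (v[0], v[1])
                       for pt, v in data["pt_counts"].items()},
            planted_effects=data["planted_effects"],
        )


@dataclass
class SyntheticSample:
    """In-memory generated tables plus their ground truth."""

    demo: List[RawReport]
    drug: List[DrugRecord]
    reac: List[ReactionRecord]
    indi: List[IndicationRecord]
    outc: List[OutcomeRecord]
    ground_truth: GroundTruth


_AGE_BOUNDS = {0: (1, 18), 1: (18, 45), 2: (45, 65), 3: (65, 96)}


def _yyyymmdd(ordinal: int) -> int:
    d = _dt.date.fromordinal(int(ordinal))
    return d.year * 10000 + d.month * 100 + d.day


def sample(config: SyntheticConfig) -> SyntheticSample:
    """Draw one complete synthetic dataset (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    vocab = config.vocabulary
    pts = [pt for pt, _, _ in vocab]
    p_base = np.array([p for _, _, p in vocab])
    theta = np.array([float(config.planted_effects.get(pt, 1.0))
                      for pt in pts])
    p_target = planted_event_probability(p_base, theta)

    case_ids = 1_000_001 + np.arange(n)
    primary_ids = case_ids * 10 + 5
    start = _dt.date(2020, 1, 1).toordinal()
    end = _dt.date(2022, 12, 31).toordinal()
    ordinals = rng.integers(start, end + 1, size=n)

    is_target = rng.random(n) < config.target_share
    is_covid = rng.random(n) >= config.non_covid_rate

    age_cat = rng.choice(5, size=n, p=config.age_probs)
    age_years = np.zeros(n, dtype=np.int64)
    for cat, (lo, hi) in _AGE_BOUNDS.items():
        mask = age_cat == cat
        age_years[mask] = rng.integers(lo, hi, size=int(mask.sum()))
    # some infants are coded in months to exercise unit conversion
    months_coded = (age_cat == 0) & (rng.random(n) < 0.25)
    age_months = rng.integers(1, 24, size=n)

    sex_cat = rng.choice(3, size=n, p=config.sex_probs)
    occ_cat = rng.choice(6, size=n, p=config.occupation_probs)
    country_cat = rng.choice(4, size=n, p=config.country_probs)
    other_countries = ("GB", "FR", "DE", "IT", "CA", "AU", "BR", "IN",
                       "KR", "ES")
    other_country_idx = rng.integers(0, len(other_countries), size=n)

    indication_idx = rng.choice(len(_SMQ_TERMS_ORDERED), size=n,
                                p=INDICATION_WEIGHTS)
    non_covid_idx = rng.integers(0, len(NON_COVID_INDICATIONS), size=n)

    target_name_idx = rng.integers(0, len(TARGET_DRUG_NAMES), size=n)
    comparator_name_idx = rng.integers(0, len(COMPARATOR_DRUG_NAMES), size=n)
    dosage_cat = rng.choice(4, size=n, p=config.dosage_probs)
    has_concomitant = rng.random(n) < config.concomitant_rate
    concomitant_idx = rng.integers(0, len(CONCOMITANT_DRUG_NAMES), size=n)

    p_row = np.where(is_target[:, None], p_target[None, :], p_base[None, :])
    occur = rng.random((n, len(pts))) < p_row

    has_excluded = rng.random(n) < config.excluded_event_rate
    excluded_idx = rng.integers(0, len(EXCLUDED_EVENT_TERMS), size=n)

    outcome_occur = (rng.random((n, 7))
                     < np.array(config.outcome_probs)[None, :])
    outcome_codes = ("DE", "LT", "HO", "DS", "RI", "CA", "OT")

    dup_mask = rng.random(n) < config.duplicate_version_rate
    dup_flavor = rng.integers(0, 3, size=n)
    dup_day_offset = rng.integers(1, 31, size=n)

    sexes = ("F", "M", None)
    occupations = ("MD", "PH", "OT", "CN", "LW", None)
    dose_fields = ((800.0, "MG", "BID"), (400.0, "MG", "BID"),
                   (1200.0, "MG", "BID"), (None, None, None))

    demo: List[RawReport] = []
    drug: List[DrugRecord] = []
    reac: List[ReactionRecord] = []
    indi: List[IndicationRecord] = []
    outc: List[OutcomeRecord] = []

    for i in range(n):
        pid = int(primary_ids[i])
        cid = int(case_ids[i])
        fda_dt = _yyyymmdd(ordinals[i])
        if months_coded[i]:
            age_value, age_code = float(age_months[i]), "MON"
        elif age_cat[i] == 4:
            age_value, age_code = None, None
        else:
            age_value, age_code = float(age_years[i]), "YR"
        if country_cat[i] == 0:
            country: Optional[str] = "US"
        elif country_cat[i] == 1:
            country = "JP"
        elif country_cat[i] == 2:
            country = other_countries[other_country_idx[i]]
        else:
            country = None
        report = RawReport(
            primary_id=pid, case_id=cid, fda_dt=fda_dt,
            age_value=age_value, age_code=age_code,
            sex=sexes[sex_cat[i]],
            occupation_code=occupations[occ_cat[i]],
            reporter_country=country)
        demo.append(report)

        if dup_mask[i]:
            earlier = _yyyymmdd(ordinals[i] - int(dup_day_offset[i]))
            if dup_flavor[i] == 0:          # exact duplicate row
                demo.append(report)
            elif dup_flavor[i] == 1:        # superseded earlier version
                demo.append(RawReport(
                    primary_id=pid - 1, case_id=cid, fda_dt=earlier,
                    age_value=age_value, age_code=age_code,
                    sex=report.sex, occupation_code=report.occupation_code,
                    reporter_country=country))
            else:                           # same version, earlier receipt
                demo.append(RawReport(
                    primary_id=pid, case_id=cid, fda_dt=earlier,
                    age_value=age_value, age_code=age_code,
                    sex=report.sex, occupation_code=report.occupation_code,
                    reporter_country=country))

        if is_target[i]:
            name = TARGET_DRUG_NAMES[target_name_idx[i]]
            amount, unit, freq = dose_fields[dosage_cat[i]]
            drug.append(DrugRecord(
                primary_id=pid, drug_seq=1, role_code="PS", drug_name=name,
                product_ai="MOLNUPIRAVIR", dose_amount=amount,
                dose_unit=unit, dose_frequency=freq))
        else:
            name = COMPARATOR_DRUG_NAMES[comparator_name_idx[i]]
            drug.append(DrugRecord(
                primary_id=pid, drug_seq=1, role_code="PS", drug_name=name,
                product_ai=name))
        if has_concomitant[i]:
            drug.append(DrugRecord(
                primary_id=pid, drug_seq=2, role_code="C",
                drug_name=CONCOMITANT_DRUG_NAMES[concomitant_idx[i]]))

        if is_covid[i]:
            indication = _SMQ_TERMS_ORDERED[indication_idx[i]]
        else:
            indication = NON_COVID_INDICATIONS[non_covid_idx[i]]
        indi.append(IndicationRecord(
            primary_id=pid, indication_drug_seq=1, indication_pt=indication))

        for j in np.flatnonzero(occur[i]):
            reac.append(ReactionRecord(primary_id=pid, event_pt=pts[j]))
        if has_excluded[i]:
            reac.append(ReactionRecord(
                primary_id=pid,
                event_pt=EXCLUDED_EVENT_TERMS[excluded_idx[i]]))

        for j in np.flatnonzero(outcome_occur[i]):
            outc.append(OutcomeRecord(primary_id=pid,
                                      outcome_code=outcome_codes[j]))

    covid_target = is_covid & is_target
    covid_comp = is_covid & ~is_target
    a_counts = occur[covid_target].sum(axis=0)
    c_counts = occur[covid_comp].sum(axis=0)
    ground_truth = GroundTruth(
        seed=config.seed,
        n_target=int(covid_target.sum()),
        n_comparator=int(covid_comp.sum()),
        target_pairs=int(a_counts.sum()),
        comparator_pairs=int(c_counts.sum()),
        pt_counts={pt: (int(a_counts[j]), int(c_counts[j]))
                   for j, pt in enumerate(pts)},
        planted_effects={pt: float(t)
                         for pt, t in config.planted_effects.items()},
    )
    return SyntheticSample(demo=demo, drug=drug, reac=reac, indi=indi,
                           outc=outc, ground_truth=ground_truth)


def generate(config: SyntheticConfig, outdir) -> Dict[str, Path]:
    """Write the five FAERS ASCII tables plus the ground-truth ledger.

    Returns a mapping of table kind (and ``"ground_truth"``) to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = sample(config)
    paths = {
        "DEMO": faers_io.write_table(data.demo, outdir / "DEMO.txt",
                                     TableKind.DEMO),
        "DRUG": faers_io.write_table(data.drug, outdir / "DRUG.txt",
                                     TableKind.DRUG),
        "REAC": faers_io.write_table(data.reac, outdir / "REAC.txt",
                                     TableKind.REAC),
        "INDI": faers_io.write_table(data.indi, outdir / "INDI.txt",
                                     TableKind.INDI),
        "OUTC": faers_io.write_table(data.outc, outdir / "OUTC.txt",
                                     TableKind.OUTC),
        "ground_truth": data.ground_truth.to_json(
            outdir / "ground_truth.json"),
    }
    return paths


@dataclass
class GroundTruthReport:
    """Outcome of checking pipeline output against the ledger."""

    ok: bool
    mismatches: List[str]
    ror_comparison: pd.DataFrame


def ground_truth_check(cohort: Sequence[SafetyCase],
                       ledger: GroundTruth) -> GroundTruthReport:
    """Verify a pipeline run against the generator's ledger.

    Group sizes, total pair counts and per-PT (a, c) counts must match
    exactly; estimated RORs for the planted PTs are tabulated against
    their true θ (report-count denominator, under which ROR estimates
    θ consistently).
    """
    from .signals import build_contingency, event_pair_counts, ror

    counts, pair_totals, report_totals = event_pair_counts(cohort)
    mismatches: List[str] = []

    def check(label: str, got, expected):
        if got != expected:
            mismatches.append(f"{label}: pipeline {got} != ledger {expected}")

    check("n_target", report_totals[0], ledger.n_target)
    check("n_comparator", report_totals[1], ledger.n_comparator)
    check("target_pairs", pair_totals[0], ledger.target_pairs)
    check("comparator_pairs", pair_totals[1], ledger.comparator_pairs)
    for pt, expected in sorted(ledger.pt_counts.items()):
        check(f"counts[{pt}]", counts.get(pt, (0, 0)), tuple(expected))
    for pt in sorted(counts):
        if pt not in ledger.pt_counts:
            mismatches.append(f"unexpected PT in pipeline output: {pt}")

    rows = []
    for pt, theta in sorted(ledger.planted_effects.items()):
        observed = counts.get(pt, (0, 0))
        estimate = ror(build_contingency(observed, report_totals))
        rows.append({"event_pt": pt, "theta": theta, "a": observed[0],
                     "c": observed[1], "ror_reports": estimate})
    return GroundTruthReport(
        ok=not mismatches, mismatches=mismatches,
        ror_comparison=pd.DataFrame(
            rows, columns=["event_pt", "theta", "a", "c", "ror_reports"]))
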