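"""Cohort data model, event-CSV readers/writers, and record-level QC rules.

The analysis dataset is a NONMEM-style long table: one row per event, where an
event is either a covariate declaration (``EVTYPE=COV``), a steady-state serum
valproic-acid concentration (``CONC``) or a serum gamma-glutamyltransferase
measurement (``GGT``).  Concentrations are in mg/L (equivalently ug/mL), times
in hours since the last administration, dates ISO-8601.

Quality-control rules implemented here:

* concentrations below the assay's lower limit of quantification (1 mg/L by
  default) are flagged as suspected temporary noncompliance and excluded;
* gamma-GT measurements are dichotomised against an age- and sex-stratified
  upper limit of normal (ULN), elevation meaning a value strictly above the
  limit;
* measurements taken in the first months of therapy (default six) are dropped
  to avoid transient start-of-therapy elevations;
* genotype distributions are checked for Hardy-Weinberg equilibrium with a
  one-degree-of-freedom Pearson chi-square test.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectCovariates",
    "ConcentrationRecord",
    "GGTRecord",
    "ULNTable",
    "Cohort",
    "CohortFormatError",
    "CohortIntegrityError",
    "ULNCoverageError",
    "load_cohort",
    "write_cohort",
    "load_uln_table",
    "default_uln_table",
    "flag_noncompliance",
    "binarize_ggt",
    "filter_early_ggt",
    "genotype_qc",
    "qc_report",
    "DAYS_PER_MONTH",
]

SEXES = ("male", "female")
SOD2_GENOTYPES = ("ValVal", "ValAla", "AlaAla")
CYP2C9_GENOTYPES = ("*1/*1", "*1/*3", "*3/*3")
CYP2C19_GROUPS = ("homEM", "hetEM", "PM")
GST_GENOTYPES = ("null", "present")
COMEDS = ("CBZ", "CLB", "PB", "PHT", "TPM", "ZNS", "GBP")

#: mean Gregorian month length used to convert day offsets to months
DAYS_PER_MONTH = 30.4375

DEFAULT_LOQ = 1.0  # mg/L, assay lower limit of quantification
DEFAULT_MIN_MONTHS = 6.0


class CohortFormatError(ValueError):
    """Malformed event CSV (missing columns, unparseable rows)."""


class CohortIntegrityError(ValueError):
    """Referential problems: records pointing at unknown subjects."""


class ULNCoverageError(LookupError):
    """No upper-limit-of-normal band covers a (sex, age) pair."""


@dataclass(frozen=True)
class SubjectCovariates:
    subject_id: str
    age: float  # years
    sex: str
    body_weight: float  # kg
    daily_dose: float  # mg/day
    sod2: str
    cyp2c9: str
    cyp2c19: str
    gstm1: str
    gstt1: str
    intellectual_disability: bool
    comeds: frozenset = frozenset()
    vpa_start_date: _dt.date = _dt.date(2000, 1, 1)

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be positive, got {self.body_weight}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.sod2 not in SOD2_GENOTYPES:
            raise ValueError(f"sod2 must be one of {SOD2_GENOTYPES}, got {self.sod2!r}")
        if self.cyp2c9 not in CYP2C9_GENOTYPES:
            raise ValueError(f"cyp2c9 must be one of {CYP2C9_GENOTYPES}")
        if self.cyp2c19 not in CYP2C19_GROUPS:
            raise ValueError(f"cyp2c19 must be one of {CYP2C19_GROUPS}")
        if self.gstm1 not in GST_GENOTYPES or self.gstt1 not in GST_GENOTYPES:
            raise ValueError("gstm1/gstt1 must be 'null' or 'present'")
        unknown = set(self.comeds) - set(COMEDS)
        if unknown:
            raise ValueError(f"unknown co-medications: {sorted(unknown)}")
        object.__setattr__(self, "comeds", frozenset(self.comeds))

    @property
    def sod2_valval(self) -> int:
        """Val/Val indicator; Ala carriers (Val/Ala, Ala/Ala) are pooled as 0."""
        return int(self.sod2 == "ValVal")


@dataclass(frozen=True)
class ConcentrationRecord:
    subject_id: str
    time_after_last_dose: float  # h
    dose_per_administration: float  # mg
    dosing_interval: float  # h
    value: float  # mg/L
    steady_state: bool = True

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("concentration must be non-negative")
        if self.dosing_interval <= 0:
            raise ValueError("dosing interval must be positive")


@dataclass(frozen=True)
class GGTRecord:
    subject_id: str
    measurement_date: _dt.date
    value: float  # IU/L
    months_since_vpa_start: float
    elevated: int | None = None  # set by load_cohort / binarize_ggt only

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("gamma-GT value must be positive")
        if self.elevated not in (None, 0, 1):
            raise ValueError("elevated must be 0, 1 or unset")


class ULNTable:
    """Age- and sex-stratified upper limits of normal for serum gamma-GT.

    Rows are ``(sex, age_lower, age_upper, uln)``; a band covers ages in
    ``[age_lower, age_upper)``.  Bands within a sex must not overlap.
    """

    def __init__(self, rows: Iterable[tuple[str, float, float, float]]):
        self.rows = [(str(s), float(lo), float(hi), float(u)) for s, lo, hi, u in rows]
        for s, lo, hi, u in self.rows:
            if s not in SEXES:
                raise ValueError(f"ULN sex must be in {SEXES}, got {s!r}")
            if not (lo < hi) or u <= 0:
                raise ValueError("ULN bands need age_lower < age_upper and uln > 0")
        for sex in SEXES:
            bands = sorted((lo, hi) for s, lo, hi, _ in self.rows if s == sex)
            for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
                if lo2 < hi1:
                    raise ValueError(f"overlapping ULN bands for {sex}")

    def lookup(self, sex: str, age: float) -> float:
        for s, lo, hi, u in self.rows:
            if s == sex and lo <= age < hi:
                return u
        raise ULNCoverageError(f"no ULN band covers sex={sex!r}, age={age:g}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["SEX", "AGE_LO", "AGE_HI", "ULN"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_uln_table() -> ULNTable:
    """A synthetic default ULN table (IU/L), NOT an authoritative clinical reference.

    Adult limits differ by sex; a single paediatric band is used below 16 years.
    Real analyses should supply the laboratory's own stratified limits.
    """
    return ULNTable(
        [
            ("male", 0.0, 16.0, 25.0),
            ("male", 16.0, 200.0, 70.0),
            ("female", 0.0, 16.0, 25.0),
            ("female", 16.0, 200.0, 40.0),
        ]
    )


def load_uln_table(path) -> ULNTable:
    df = pd.read_csv(path)
    required = {"SEX", "AGE_LO", "AGE_HI", "ULN"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"ULN table missing columns: {sorted(missing)}")
    return ULNTable(df[["SEX", "AGE_LO", "AGE_HI", "ULN"]].itertuples(index=False, name=None))


@dataclass
class Cohort:
    subjects: list = field(default_factory=list)
    pk_records: list = field(default_factory=list)
    ggt_records: list = field(default_factory=list)

    def __post_init__(self):
        self._check_integrity()

    def _check_integrity(self):
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise CohortIntegrityError("duplicate subject ids")
        for rec in list(self.pk_records) + list(self.ggt_records):
            if rec.subject_id not in ids:
                raise CohortIntegrityError(
                    f"record references unknown subject {rec.subject_id!r}"
                )

    def subject(self, subject_id: str) -> SubjectCovariates:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            d = dataclasses.asdict(s)
            d["comeds"] = "+".join(sorted(s.comeds))
            rows.append(d)
        return pd.DataFrame(rows)

    def __eq__(self, other):
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and self.pk_records == other.pk_records
            and self.ggt_records == other.ggt_records
        )


# ---------------------------------------------------------------------------
# event CSV IO

CSV_COLUMNS = [
    "ID", "EVTYPE", "DATE", "TIME", "AMT", "II", "SS", "DV_CONC", "DV_GGT",
    "AGE", "SEX", "WT", "DOSE", "SOD2", "CYP2C9", "CYP2C19", "GSTM1", "GSTT1",
    "INTDIS", "COMEDS", "VPA_START",
]

_REQUIRED_COLUMNS = ["ID", "EVTYPE", "DV_CONC", "DV_GGT", "AGE", "SEX", "WT", "DOSE"]


def write_cohort(cohort: Cohort, path) -> None:
    """Serialize a cohort to the event CSV dialect read by :func:`load_cohort`."""
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "ID": s.subject_id, "EVTYPE": "COV", "AGE": s.age, "SEX": s.sex,
                "WT": s.body_weight, "DOSE": s.daily_dose, "SOD2": s.sod2,
                "CYP2C9": s.cyp2c9, "CYP2C19": s.cyp2c19, "GSTM1": s.gstm1,
                "GSTT1": s.gstt1, "INTDIS": int(s.intellectual_disability),
                "COMEDS": "+".join(sorted(s.comeds)),
                "VPA_START": s.vpa_start_date.isoformat(),
            }
        )
    for r in cohort.pk_records:
        rows.append(
            {
                "ID": r.subject_id, "EVTYPE": "CONC", "TIME": r.time_after_last_dose,
                "AMT": r.dose_per_administration, "II": r.dosing_interval,
                "SS": int(r.steady_state), "DV_CONC": r.value,
            }
        )
    for r in cohort.ggt_records:
        rows.append(
            {
                "ID": r.subject_id, "EVTYPE": "GGT",
                "DATE": r.measurement_date.isoformat(), "DV_GGT": r.value,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _parse_date(x) -> _dt.date:
    return _dt.date.fromisoformat(str(x))


def load_cohort(path, uln: ULNTable) -> Cohort:
    """Read an event CSV into a validated :class:`Cohort`.

    Gamma-GT rows are dichotomised against *uln* on load; months since the
    start of therapy are derived from ``DATE`` and the subject's ``VPA_START``.
    Malformed rows are reported with their (1-based, header-exclusive) row
    numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep_default_na: 'null' is a legitimate GST genotype, not a missing value
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required columns: {missing}")

    subjects: dict[str, SubjectCovariates] = {}
    pk_records: list[ConcentrationRecord] = []
    ggt_rows: list[tuple[int, str, _dt.date, float]] = []
    bad_rows: list[str] = []

    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        ev = str(row["EVTYPE"])
        try:
            if ev == "COV":
                comeds = str(row.get("COMEDS") or "")
                comeds = frozenset(c for c in comeds.split("+") if c) if comeds != "nan" else frozenset()
                subjects[str(row["ID"])] = SubjectCovariates(
                    subject_id=str(row["ID"]), age=float(row["AGE"]),
                    sex=str(row["SEX"]), body_weight=float(row["WT"]),
                    daily_dose=float(row["DOSE"]), sod2=str(row["SOD2"]),
                    cyp2c9=str(row["CYP2C9"]), cyp2c19=str(row["CYP2C19"]),
                    gstm1=str(row["GSTM1"]), gstt1=str(row["GSTT1"]),
                    intellectual_disability=bool(int(float(row["INTDIS"]))),
                    comeds=comeds, vpa_start_date=_parse_date(row["VPA_START"]),
                )
            elif ev == "CONC":
                pk_records.append(
                    ConcentrationRecord(
                        subject_id=str(row["ID"]),
                        time_after_last_dose=float(row["TIME"]),
                        dose_per_administration=float(row["AMT"]),
                        dosing_interval=float(row["II"]),
                        value=float(row["DV_CONC"]),
                        steady_state=bool(int(float(row["SS"]))),
                    )
                )
            elif ev == "GGT":
                ggt_rows.append((i, str(row["ID"]), _parse_date(row["DATE"]), float(row["DV_GGT"])))
            else:
                bad_rows.append(f"row {i}: unknown EVTYPE {ev!r}")
        except (ValueError, TypeError, KeyError) as exc:
            bad_rows.append(f"row {i}: {exc}")
    if bad_rows:
        raise CohortFormatError("; ".join(bad_rows))

    ggt_records = []
    for i, sid, date, value in ggt_rows:
        subj = subjects.get(sid)
        if subj is None:
            raise CohortIntegrityError(f"row {i}: gamma-GT record for unknown subject {sid!r}")
        months = (date - subj.vpa_start_date).days / DAYS_PER_MONTH
        ggt_records.append(
            GGTRecord(
                subject_id=sid, measurement_date=date, value=value,
                months_since_vpa_start=months,
                elevated=binarize_ggt(value, subj.age, subj.sex, uln),
            )
        )
    return Cohort(list(subjects.values()), pk_records, ggt_records)


# ---------------------------------------------------------------------------
# filtering / QC operations

def flag_noncompliance(
    records: Sequence[ConcentrationRecord], loq: float = DEFAULT_LOQ
) -> tuple[list, list]:
    """Partition concentration records into (kept, excluded) at the LOQ.

    Concentrations below the lower limit of quantification are treated as
    suspected temporary noncompliance and excluded from estimation; order is
    preserved and the two lists partition the input.
    """
    if loq <= 0:
        raise ValueError(f"loq must be positive, got {loq}")
    kept = [r for r in records if r.value >= loq]
    excluded = [r for r in records if r.value < loq]
    return kept, excluded


def binarize_ggt(value: float, age: float, sex: str, uln: ULNTable) -> int:
    """1 if *value* strictly exceeds the matching ULN band, else 0.

    Boundary values (exactly at the limit) count as normal.
    """
    return int(value > uln.lookup(sex, age))


def filter_early_ggt(
    records: Sequence[GGTRecord], min_months: float = DEFAULT_MIN_MONTHS
) -> list:
    """Drop gamma-GT records taken before *min_months* of therapy.

    Records at exactly *min_months* are retained (the exclusion window is the
    half-open interval [0, min_months)).
    """
    if min_months < 0:
        raise ValueError("min_months must be >= 0")
    return [r for r in records if r.months_since_vpa_start >= min_months]


def genotype_qc(counts: tuple[int, int, int]) -> tuple[float, float, float]:
    """Minor-allele frequency and Hardy-Weinberg Pearson chi-square for a biallelic locus.

    *counts* are genotype counts (n_AA, n_Aa, n_aa) with 'a' the minor allele.
    Returns ``(maf, chi2, p)`` where chi2 is the 1-df Pearson statistic against
    the HWE expected genotype counts and p its upper-tail probability.
    """
    n_aa_major, n_het, n_minor = (int(c) for c in counts)
    if min(n_aa_major, n_het, n_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_aa_major + n_het + n_minor
    if total == 0:
        raise ValueError("total genotype count must be positive")
    q = (n_het + 2 * n_minor) / (2 * total)
    p_allele = 1.0 - q
    expected = np.array([p_allele**2, 2 * p_allele * q, q**2]) * total
    observed = np.array([n_aa_major, n_het, n_minor], dtype=float)
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    pval = float(stats.chi2.sf(chi2, df=1))
    return q, chi2, pval


def qc_report(cohort: Cohort) -> dict:
    """Allele frequencies and HWE tests for the cohort's genotyped loci."""
    subs = cohort.subjects

    def counts(attr, levels):
        vals = [getattr(s, attr) for s in subs]
        return tuple(vals.count(level) for level in levels)

    report = {"n_subjects": cohort.n_subjects, "loci": {}}
    for locus, attr, levels in [
        ("SOD2_Val16Ala", "sod2", SOD2_GENOTYPES),
        ("CYP2C9_star3", "cyp2c9", CYP2C9_GENOTYPES),
        ("CYP2C19_variant", "cyp2c19", CYP2C19_GROUPS),
    ]:
        c = counts(attr, levels)
        maf, chi2, p = genotype_qc(c)
        report["loci"][locus] = {
            "genotype_counts": list(c),
            "minor_allele_freq": maf,
            "hwe_chi2": chi2,
            "hwe_p": p,
        }
    for locus, attr in [("GSTM1", "gstm1"), ("GSTT1", "gstt1")]:
        n_null = sum(getattr(s, attr) == "null" for s in subs)
        report["loci"][locus] = {"null_fraction": n_null / max(len(subs), 1)}
    return report


def write_qc_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
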