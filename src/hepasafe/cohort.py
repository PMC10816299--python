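"""Patient records, liver-function scores, and cohort CSV I/O.

The record layout mirrors what is collected before a right hemi-hepatectomy:
demographics, preoperative labs, CT-volumetry-derived hemi-liver volumes, the
actually resected volume, and postoperative day-5 prothrombin activity (PT%)
and serum bilirubin, from which the 50-50 definition of post-hepatectomy
liver failure (PHLF) is evaluated.

Three liver-function scores are computed from the labs:

* MELD  = 3.78*ln(TB mg/dL) + 11.2*ln(INR) + 9.57*ln(Cr mg/dL) + 6.43
* ALBI  = 0.66*log10(TB umol/L) - 0.085*(albumin g/L)
* APRI  = (AST / reference AST * 100) / PLT(10^9/L), reference AST = 40 U/L

All score functions are pure, accept scalars or numpy arrays, and raise
``DomainError`` on non-positive inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "PatientRecord",
    "DerivedScores",
    "FeatureVector",
    "DEFAULT_FEATURE_NAMES",
    "compute_meld",
    "compute_albi",
    "compute_apri",
    "compute_flr",
    "compute_rlwr",
    "classify_phlf_5050",
    "tb_mgdl_to_umol",
    "albumin_gdl_to_gl",
    "derive_scores",
    "assemble_features",
    "read_cohort",
    "write_cohort",
]

#: mg/dL -> umol/L conversion factor for bilirubin.
TB_MGDL_TO_UMOL = 17.1

SEXES = ("male", "female")
DIAGNOSES = ("HCC", "colon_liver_meta", "iCCC", "eCCC", "liver_donor", "other")


class DomainError(ValueError):
    """An input lies outside the physiological/mathematical domain."""


def _check_positive(**named: object) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")


def _check_non_negative(**named: object) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DomainError(f"{name} must be non-negative and finite, got {value!r}")


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

def compute_meld(tb: float, inr: float, cr: float, *, clamp: bool = False):
    """Model for End-Stage Liver Disease score.

    Parameters
    ----------
    tb : total serum bilirubin, mg/dL.
    inr : prothrombin time international normalized ratio.
    cr : serum creatinine, mg/dL.
    clamp : apply the conventional clamp of each input to >= 1 before the
        logarithms. Off by default, i.e. the bare log-linear formula.
    """
    _check_positive(tb=tb, inr=inr, cr=cr)
    tb, inr, cr = (np.asarray(v, dtype=float) for v in (tb, inr, cr))
    if clamp:
        tb, inr, cr = (np.maximum(v, 1.0) for v in (tb, inr, cr))
    out = 3.78 * np.log(tb) + 11.2 * np.log(inr) + 9.57 * np.log(cr) + 6.43
    return float(out) if out.ndim == 0 else out


def compute_albi(tb_umol: float, albumin_g_l: float):
    """Albumin-bilirubin grade on its original unit convention.

    ``tb_umol`` is bilirubin in umol/L and ``albumin_g_l`` albumin in g/L;
    use :func:`tb_mgdl_to_umol` / :func:`albumin_gdl_to_gl` to convert from
    US customary units.
    """
    _check_positive(tb_umol=tb_umol)
    _check_positive(albumin_g_l=albumin_g_l)
    tb_umol = np.asarray(tb_umol, dtype=float)
    out = np.log10(tb_umol) * 0.66 + np.asarray(albumin_g_l, dtype=float) * (-0.085)
    return float(out) if out.ndim == 0 else out


def compute_apri(ast: float, plt: float, ref_ast: float = 40.0):
    """AST-to-platelet ratio index; ``plt`` in 10^9/L (== 10^3/uL), AST in U/L."""
    _check_positive(ast=ast, plt=plt, ref_ast=ref_ast)
    ast = np.asarray(ast, dtype=float)
    plt = np.asarray(plt, dtype=float)
    out = (ast / ref_ast * 100.0) / plt
    return float(out) if out.ndim == 0 else out


def compute_flr(lt_volume: float, rt_volume: float):
    """Future liver remnant percentage for a right hemi-hepatectomy.

    The remnant is the left hemi-liver: FLR% = 100 * Lt / (Lt + Rt).
    """
    _check_positive(lt_volume=lt_volume, rt_volume=rt_volume)
    lt = np.asarray(lt_volume, dtype=float)
    rt = np.asarray(rt_volume, dtype=float)
    out = 100.0 * lt / (lt + rt)
    return float(out) if out.ndim == 0 else out


def compute_rlwr(lt_volume: float, weight: float):
    """Remnant-liver-to-body-weight ratio in percent (1 mL liver ~ 1 g)."""
    _check_positive(lt_volume=lt_volume, weight=weight)
    lt = np.asarray(lt_volume, dtype=float)
    wt = np.asarray(weight, dtype=float)
    out = 100.0 * lt / (wt * 1000.0)
    return float(out) if out.ndim == 0 else out


def classify_phlf_5050(pod5_pt_pct: float, pod5_sb: float):
    """50-50 criteria: PT < 50% AND serum bilirubin > 50 umol/L on day 5.

    Both inequalities are strict; boundary values classify as no-PHLF.
    """
    _check_non_negative(pod5_pt_pct=pod5_pt_pct, pod5_sb=pod5_sb)
    pt = np.asarray(pod5_pt_pct, dtype=float)
    sb = np.asarray(pod5_sb, dtype=float)
    out = (pt < 50.0) & (sb > 50.0)
    return bool(out) if out.ndim == 0 else out


def tb_mgdl_to_umol(tb_mgdl: float):
    """Convert total bilirubin from mg/dL to umol/L (factor 17.1)."""
    return np.asarray(tb_mgdl, dtype=float) * TB_MGDL_TO_UMOL


def albumin_gdl_to_gl(albumin_gdl: float):
    """Convert albumin from g/dL to g/L."""
    return np.asarray(albumin_gdl, dtype=float) * 10.0


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One patient's preoperative data plus surgical and day-5 outcomes.

    Labs are stored in the units they are reported in clinically: TB and
    Cr in mg/dL, albumin in g/dL, PLT in 10^3/uL, volumes in mL. POD5
    fields and the resected volume may be ``None`` preoperatively.
    """

    patient_id: str
    age: float
    sex: str
    weight: float
    bmi: float
    asa_class: int
    htn: bool
    dm: bool
    hbv: bool
    hcv: bool
    alcoholism: bool
    diagnosis: str
    wbc: float
    neutrophil: float
    plt: float
    pt_inr: float
    pt_pct: float
    tb: float
    albumin: float
    ast: float
    alt: float
    cr: float
    hs_crp: float
    rt_volume: float
    lt_volume: float
    resected_volume: float | None = None
    pod5_pt_pct: float | None = None
    pod5_sb: float | None = None
    phlf: bool | None = None

    def validate(self) -> "PatientRecord":
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise DomainError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        if self.asa_class not in (1, 2, 3):
            raise DomainError(f"asa_class must be in {{1,2,3}}, got {self.asa_class!r}")
        _check_positive(
            age=self.age, weight=self.weight, bmi=self.bmi, wbc=self.wbc,
            neutrophil=self.neutrophil, plt=self.plt, pt_inr=self.pt_inr,
            pt_pct=self.pt_pct, tb=self.tb, albumin=self.albumin, ast=self.ast,
            alt=self.alt, cr=self.cr, hs_crp=self.hs_crp,
            rt_volume=self.rt_volume, lt_volume=self.lt_volume,
        )
        if not 0 < self.pt_pct <= 200:
            raise DomainError(f"pt_pct must lie in (0, 200], got {self.pt_pct}")
        if self.resected_volume is not None:
            _check_positive(resected_volume=self.resected_volume)
        if self.pod5_pt_pct is not None and self.pod5_sb is not None:
            expected = classify_phlf_5050(self.pod5_pt_pct, self.pod5_sb)
            if self.phlf is not None and bool(self.phlf) != expected:
                raise DomainError(
                    f"phlf={self.phlf} inconsistent with POD5 values "
                    f"(PT%={self.pod5_pt_pct}, SB={self.pod5_sb} -> {expected})"
                )
        return self


@dataclass(frozen=True)
class DerivedScores:
    """Scores and volumetry ratios derived from a :class:`PatientRecord`."""

    meld: float
    albi: float
    apri: float
    flr_pct: float
    rlwr_pct: float


def derive_scores(record: PatientRecord) -> DerivedScores:
    """Compute MELD/ALBI/APRI and FLR%/RLWR% from a record's raw fields."""
    return DerivedScores(
        meld=compute_meld(record.tb, record.pt_inr, record.cr),
        albi=compute_albi(
            float(tb_mgdl_to_umol(record.tb)), float(albumin_gdl_to_gl(record.albumin))
        ),
        apri=compute_apri(record.ast, record.plt),
        flr_pct=compute_flr(record.lt_volume, record.rt_volume),
        rlwr_pct=compute_rlwr(record.lt_volume, record.weight),
    )


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

#: Canonical 23-feature list fed to the regressors. Diagnosis is collected
#: but excluded; Rt. volume, FLR% and RLWR% are excluded because together
#: with Lt. volume they nearly determine the resected volume (label leakage).
DEFAULT_FEATURE_NAMES: tuple[str, ...] = (
    "age", "sex", "bmi", "asa_class", "htn", "dm", "hbv", "hcv", "alcoholism",
    "wbc", "neutrophil", "plt", "pt_inr", "pt_pct", "tb", "ast", "alt", "cr",
    "hs_crp", "apri", "albi", "meld", "lt_volume",
)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric feature vector with its canonical name list."""

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if any(not np.isfinite(v) for v in self.values):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _feature_value(record: PatientRecord, scores: DerivedScores, name: str) -> float:
    if name == "sex":
        return 1.0 if record.sex == "male" else 0.0
    if name in ("htn", "dm", "hbv", "hcv", "alcoholism"):
        return float(bool(getattr(record, name)))
    if name in ("apri", "albi", "meld"):
        return float(getattr(scores, name))
    if name == "flr_pct" or name == "rlwr_pct":
        return float(getattr(scores, name))
    return float(getattr(record, name))


def assemble_features(
    record: PatientRecord,
    scores: DerivedScores | None = None,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> FeatureVector:
    """Build the ordered feature vector for one patient.

    Categoricals are encoded minimally: sex male=1/female=0, comorbidity
    flags 0/1, ASA class as its integer. Scores are recomputed from the
    record when not supplied.
    """
    if scores is None:
        scores = derive_scores(record)
    missing = [
        n for n in feature_names
        if n not in ("sex", "apri", "albi", "meld", "flr_pct", "rlwr_pct")
        and getattr(record, n, None) is None
    ]
    if missing:
        raise DomainError(f"record {record.patient_id!r} missing fields: {missing}")
    values = tuple(_feature_value(record, scores, n) for n in feature_names)
    return FeatureVector(names=tuple(feature_names), values=values)


def cohort_to_arrays(
    records: Sequence[PatientRecord],
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack features and resected-volume targets for a cohort."""
    X = np.vstack([assemble_features(r, feature_names=feature_names).as_array() for r in records])
    y = np.array([r.resected_volume for r in records], dtype=float)
    if np.any(~np.isfinite(y)):
        raise DomainError("all records need a resected_volume target")
    return X, y


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = ("htn", "dm", "hbv", "hcv", "alcoholism")
_OPTIONAL_COLUMNS = ("resected_volume", "pod5_pt_pct", "pod5_sb", "phlf")
COHORT_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(PatientRecord))


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records to a UTF-8 CSV, one row per patient.

    Booleans are serialized as 0/1; absent optional fields as empty cells.
    """
    rows = []
    for rec in records:
        row = {}
        for f in fields(PatientRecord):
            val = getattr(rec, f.name)
            if f.name in _BOOL_COLUMNS or f.name == "phlf":
                val = "" if val is None else int(bool(val))
            elif val is None:
                val = ""
            row[f.name] = val
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def _parse_row(row: pd.Series, idx: int, strict: bool) -> PatientRecord:
    def get(name, caster):
        raw = row[name]
        if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
            if name in _OPTIONAL_COLUMNS:
                return None
            raise DomainError(f"row {idx}: missing value in required column {name!r}")
        try:
            return caster(raw)
        except (TypeError, ValueError) as exc:
            raise DomainError(f"row {idx}: cannot parse column {name!r}: {exc}") from exc

    def as_bool(v):
        return bool(int(v))

    kwargs = dict(
        patient_id=str(row["patient_id"]),
        age=get("age", float), sex=get("sex", str), weight=get("weight", float),
        bmi=get("bmi", float), asa_class=get("asa_class", int),
        htn=get("htn", as_bool), dm=get("dm", as_bool), hbv=get("hbv", as_bool),
        hcv=get("hcv", as_bool), alcoholism=get("alcoholism", as_bool),
        diagnosis=get("diagnosis", str),
        wbc=get("wbc", float), neutrophil=get("neutrophil", float),
        plt=get("plt", float), pt_inr=get("pt_inr", float),
        pt_pct=get("pt_pct", float), tb=get("tb", float),
        albumin=get("albumin", float), ast=get("ast", float),
        alt=get("alt", float), cr=get("cr", float), hs_crp=get("hs_crp", float),
        rt_volume=get("rt_volume", float), lt_volume=get("lt_volume", float),
        resected_volume=get("resected_volume", float),
        pod5_pt_pct=get("pod5_pt_pct", float), pod5_sb=get("pod5_sb", float),
        phlf=get("phlf", as_bool),
    )
    rec = PatientRecord(**kwargs)
    if strict:
        rec.validate()
    return rec


def read_cohort(path, *, strict: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort`.

    In strict mode unknown columns are rejected, records are validated, and
    empty cells in required columns raise. With ``strict=False`` extra
    columns are ignored and validation is skipped.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DomainError(f"cohort file missing required columns: {missing_cols}")
    if strict:
        extra = [c for c in df.columns if c not in COHORT_COLUMNS]
        if extra:
            raise DomainError(f"unknown columns in strict mode: {extra}")
    return [_parse_row(row, i, strict) for i, (_, row) in enumerate(df.iterrows())]
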