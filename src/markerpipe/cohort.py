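"""Core data containers: expression matrix and clinical cohort.

The clinical table uses day offsets from diagnosis (diagnosis = day 0) for
every date column, which keeps the statistical core free of calendar
parsing.

Clinical CSV column dictionary
------------------------------
patient_id        unique identifier
age_years         age at diagnosis (years)
wbc               white-blood-cell count (x10^9/L)
cytogenetic_risk  one of favorable / intermediate / adverse / undetermined
npm1, flt3_itd, bicebpa, tp53, runx1, asxl1
                  mutation flags (0/1)
cr_achieved       complete remission achieved (0/1)
cr_day            day of CR (empty if no CR)
relapse_day       day of relapse (empty if none; requires CR)
death_day         day of death (empty if alive at last follow-up)
last_followup_day day terminating the timeline (death day if dead)
hsct_day          day of allogeneic transplant (empty if none)
marker_value      marker measurement (NCN or RPKM scale)
marker_status     'H+' / 'H-' / '' (unset)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InvalidInputError

__all__ = ["ExpressionMatrix", "ClinicalCohort", "CLINICAL_COLUMNS"]

CLINICAL_COLUMNS = [
    "patient_id",
    "age_years",
    "wbc",
    "cytogenetic_risk",
    "npm1",
    "flt3_itd",
    "bicebpa",
    "tp53",
    "runx1",
    "asxl1",
    "cr_achieved",
    "cr_day",
    "relapse_day",
    "death_day",
    "last_followup_day",
    "hsct_day",
    "marker_value",
    "marker_status",
]

RISK_LEVELS = ("favorable", "intermediate", "adverse", "undetermined")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative expression values (RPKM scale)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidInputError("expression matrix shape does not match id lists")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InvalidInputError("expression values must be finite and >= 0")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class ClinicalCohort:
    """Per-patient clinical table; see the module docstring for columns."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"clinical table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        d = self.data
        if d["patient_id"].duplicated().any():
            raise DataIntegrityError(
                "duplicate patient ids",
                patient_ids=d.loc[d["patient_id"].duplicated(), "patient_id"],
            )
        for col in ("cr_day", "relapse_day", "death_day", "hsct_day"):
            bad = d.loc[d[col].notna() & (d[col] < 0), "patient_id"]
            if len(bad):
                raise DataIntegrityError(f"{col} before diagnosis", patient_ids=bad)
        no_cr_relapse = d["relapse_day"].notna() & (
            d["cr_day"].isna() | (d["relapse_day"] < d["cr_day"])
        )
        if no_cr_relapse.any():
            raise DataIntegrityError(
                "relapse requires a prior CR date",
                patient_ids=d.loc[no_cr_relapse, "patient_id"],
            )
        dead = d["death_day"].notna()
        mism = dead & (d["last_followup_day"] != d["death_day"])
        if mism.any():
            raise DataIntegrityError(
                "death day must terminate follow-up",
                patient_ids=d.loc[mism, "patient_id"],
            )
        if d["last_followup_day"].isna().any():
            raise DataIntegrityError(
                "every patient needs a terminating time",
                patient_ids=d.loc[d["last_followup_day"].isna(), "patient_id"],
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def marker_high(self) -> pd.Series:
        return self.data["marker_status"] == "H+"

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClinicalCohort":
        df = pd.read_csv(
            path,
            dtype={"patient_id": str, "cytogenetic_risk": str, "marker_status": str},
        )
        df["marker_status"] = df["marker_status"].fillna("")
        return cls(df)
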