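"""Symptom datasets: binary respondent-by-symptom matrices with strata.

The in-memory containers here are deliberately thin wrappers around numpy /
pandas objects.  A :class:`SymptomCodebook` fixes the symptom (column) order
once; every matrix, table and export downstream uses that order, so that
cross-stratum comparisons align by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The nine DSM major-depression criterion symptoms, in canonical order.
DEFAULT_SYMPTOMS: tuple[tuple[str, str], ...] = (
    ("DM", "depressed mood"),
    ("LI", "loss of interest or pleasure"),
    ("AW", "appetite or weight disturbance"),
    ("SD", "sleep difficulties (insomnia or hypersomnia)"),
    ("PAR", "psychomotor agitation or retardation"),
    ("FE", "fatigue or loss of energy"),
    ("FW", "feelings of worthlessness or excessive guilt"),
    ("C", "diminished ability to think or concentrate"),
    ("SU", "suicidality"),
)

#: Declared covariate levels, in display order.  Levels are declared, not
#: inferred from the data, so a typo in a covariate cell is an error rather
#: than a silent extra stratum.  Matching is case-insensitive and tolerant
#: of en-dashes in age ranges.
DEFAULT_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "age_group": ("65-74", "75-84"),
}


class ValidationError(ValueError):
    """A dataset or cell failed validation."""


class FormatError(ValueError):
    """An input file does not have the expected shape/columns."""


def _norm_level(value: object) -> str:
    return str(value).strip().lower().replace("–", "-")


@dataclass(frozen=True)
class SymptomCodebook:
    """Ordered acronym -> description mapping defining node/column order."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_SYMPTOMS

    def __post_init__(self) -> None:
        acronyms = [a for a, _ in self.entries]
        if not acronyms:
            raise ValidationError("codebook must contain at least one symptom")
        if any(not a for a in acronyms):
            raise ValidationError("codebook acronyms must be non-empty")
        if len(set(acronyms)) != len(acronyms):
            raise ValidationError(f"codebook acronyms must be unique: {acronyms}")

    @property
    def acronyms(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.entries)

    @property
    def descriptions(self) -> dict[str, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, acronym: str) -> int:
        return self.acronyms.index(acronym)

    @classmethod
    def default(cls) -> "SymptomCodebook":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "SymptomCodebook":
        """Load a codebook from a YAML or JSON file of acronym: description
        pairs (mapping order is preserved)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"codebook file {path} must contain a mapping")
        return cls(tuple((str(k), str(v)) for k, v in data.items()))


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: a covariate name and the level defining it."""

    variable: str
    level: str

    @property
    def label(self) -> str:
        return f"{self.variable}={self.level}"


@dataclass
class SymptomDataset:
    """n x p binary endorsement matrix plus per-respondent covariates.

    ``values[i, j] == 1`` means respondent ``i`` endorsed symptom ``j`` (in
    codebook order).  ``covariates`` is a DataFrame with one row per
    respondent; it may be empty (zero columns).
    """

    values: np.ndarray
    codebook: SymptomCodebook = field(default_factory=SymptomCodebook)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape[0] < 1:
            raise ValidationError("dataset must contain at least one row")
        if self.values.shape[1] != len(self.codebook):
            raise ValidationError(
                f"matrix has {self.values.shape[1]} columns but the codebook "
                f"defines {len(self.codebook)} symptoms"
            )
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at row {bad[0]}, column "
                f"{self.codebook.acronyms[bad[1]]}"
            )
        self.values = self.values.astype(np.int8)
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=pd.RangeIndex(self.n))
        else:
            if len(self.covariates) != self.n:
                raise ValidationError(
                    f"covariates have {len(self.covariates)} rows, expected {self.n}"
                )
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.codebook.acronyms))
        for col in self.covariates.columns:
            df[col] = self.covariates[col].to_numpy()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SymptomDataset":
        rows = np.asarray(rows)
        return SymptomDataset(
            self.values[rows],
            self.codebook,
            self.covariates.iloc[rows].reset_index(drop=True),
        )


def read_dataset(
    path: str | Path,
    codebook: SymptomCodebook | None = None,
    missing_policy: str = "listwise_drop",
) -> SymptomDataset:
    """Read a respondent-by-symptom CSV into a validated dataset.

    The CSV must carry a header with every codebook acronym; any other
    columns are kept as covariates.  Symptom cells must be 0 or 1.  Under
    ``missing_policy="listwise_drop"`` rows with any non-binary or missing
    symptom value are removed (the count is logged); under ``"error"`` the
    first offending cell raises :class:`ValidationError` naming its 1-based
    data row and column.
    """
    if missing_policy not in ("error", "listwise_drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    codebook = codebook or SymptomCodebook.default()
    df = pd.read_csv(path)
    missing_cols = [a for a in codebook.acronyms if a not in df.columns]
    if missing_cols:
        raise FormatError(
            f"missing symptom column(s) {missing_cols} in {path} "
            f"(found: {list(df.columns)})"
        )
    sym = df[list(codebook.acronyms)].apply(pd.to_numeric, errors="coerce")
    ok = sym.isin([0, 1]).all(axis=1) & sym.notna().all(axis=1)
    if not ok.all():
        if missing_policy == "error":
            bad_row = int(np.flatnonzero(~ok.to_numpy())[0])
            row_mask = ~(sym.iloc[bad_row].isin([0, 1]) & sym.iloc[bad_row].notna())
            bad_col = sym.columns[np.flatnonzero(row_mask.to_numpy())[0]]
            raise ValidationError(
                f"non-binary value in row {bad_row + 1}, column {bad_col}"
            )
        n_drop = int((~ok).sum())
        logger.warning("listwise_drop removed %d row(s) with non-binary symptom values", n_drop)
        df = df.loc[ok].reset_index(drop=True)
        sym = sym.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError("no complete rows remain after listwise deletion")
    cov_cols = [c for c in df.columns if c not in codebook.acronyms]
    return SymptomDataset(
        sym.to_numpy(dtype=np.int8),
        codebook,
        df[cov_cols].copy() if cov_cols else None,
    )


def write_dataset(ds: SymptomDataset, path: str | Path) -> None:
    ds.to_csv(path)


def stratify(
    ds: SymptomDataset,
    variable: str,
    levels: Iterable[str] | None = None,
) -> list[tuple[StratumSpec, SymptomDataset]]:
    """Partition the dataset by a covariate.

    Level order: the explicit ``levels`` argument if given, else the declared
    order in :data:`DEFAULT_LEVELS`, else first appearance in the data.
    Matching is case-insensitive.  Rows whose value matches no declared level
    raise :class:`ValidationError` (no silent typo-strata).
    """
    if variable not in ds.covariates.columns:
        raise KeyError(
            f"unknown covariate {variable!r}; available: "
            f"{list(ds.covariates.columns)}"
        )
    observed = ds.covariates[variable].map(_norm_level)
    if levels is None:
        levels = DEFAULT_LEVELS.get(variable)
    if levels is None:
        levels = list(dict.fromkeys(observed))  # first appearance
    levels = [_norm_level(lv) for lv in levels]
    unmatched = set(observed) - set(levels)
    if unmatched:
        raise ValidationError(
            f"covariate {variable!r} has value(s) {sorted(unmatched)} outside "
            f"the declared levels {levels}"
        )
    out = []
    for lv in levels:
        rows = np.flatnonzero((observed == lv).to_numpy())
        if rows.size:
            out.append((StratumSpec(variable, lv), ds.subset(rows)))
    return out
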