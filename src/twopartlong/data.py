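"""Long-format panel data: validation, offsets and design matrices.

The package works on tidy longitudinal data -- one row per subject-visit --
with a nonnegative outcome, real visit times that increase within subject,
named covariate columns and a strictly positive exposure offset.  Missing
covariate values are treated as ignorably missing: rows are dropped with a
logged count and the likelihoods make no further adjustment.

Covariate standardisation is deliberately the caller's job; nothing here
rescales silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "TransformSpec",
    "LongitudinalDataset",
    "read_panel",
    "inter_visit_offsets",
    "DesignMatrices",
    "build_designs",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when data violate the panel invariants."""


class ConfigurationError(ValueError):
    """Raised when column names / terms do not match the data."""


@dataclass(frozen=True)
class TransformSpec:
    """Intensity-scale transform g with its inverse; 'identity' or 'log'."""

    name: str

    def __post_init__(self):
        if self.name not in ("identity", "log"):
            raise ConfigurationError(f"unknown transform {self.name!r}")

    def forward(self, y):
        y = np.asarray(y, dtype=float)
        return np.log(y) if self.name == "log" else y

    def inverse(self, g):
        g = np.asarray(g, dtype=float)
        return np.exp(g) if self.name == "log" else g


@dataclass
class LongitudinalDataset:
    """Validated long-format panel sorted by (subject, time).

    Attributes
    ----------
    df : DataFrame with columns ``subject``, ``time``, ``outcome``,
        ``offset`` and any covariates, sorted by (subject, time).
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        for col in ("subject", "time", "outcome"):
            if col not in df.columns:
                raise ConfigurationError(f"required column {col!r} missing")
        if "offset" not in df.columns:
            df["offset"] = 1.0
        df = df.sort_values(["subject", "time"], kind="mergesort").reset_index(drop=True)
        bad = df.index[df["outcome"] < 0]
        if len(bad):
            raise ValidationError(f"negative outcomes at rows {list(bad[:10])}")
        bad = df.index[df["offset"] <= 0]
        if len(bad):
            raise ValidationError(f"nonpositive offsets at rows {list(bad[:10])}")
        if (df["time"] < 0).any():
            raise ValidationError("negative visit times")
        dup = df.duplicated(subset=["subject", "time"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["subject", "time"]]
            raise ValidationError(
                f"duplicated (subject, time) pair: ({pair['subject']}, {pair['time']})"
            )
        self.df = df
        codes, uniques = pd.factorize(df["subject"], sort=False)
        self._codes = codes
        self._subjects = uniques

    # -- basic summaries -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self._subjects)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def subject_codes(self) -> np.ndarray:
        """Dense 0..N-1 subject codes, one per row (rows subject-contiguous)."""
        return self._codes

    @property
    def visit_counts(self) -> np.ndarray:
        return np.bincount(self._codes, minlength=self.n_subjects)

    @property
    def zero_fraction(self) -> float:
        return float((self.df["outcome"].to_numpy() == 0).mean())

    @property
    def outcome(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(dtype=float)

    @property
    def offset(self) -> np.ndarray:
        return self.df["offset"].to_numpy(dtype=float)

    def require_counts(self):
        y = self.outcome
        if not np.allclose(y, np.round(y)):
            raise ValidationError("count-family outcome must be integer-valued")

    def summary(self) -> dict:
        nz = int((self.df["outcome"].to_numpy() == 0).sum())
        return {
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_zero": nz,
            "zero_fraction": self.zero_fraction,
            "zero_percent": round(100.0 * nz / self.n_obs, 1),
        }

    def write_csv(self, path):
        self.df.to_csv(path, index=False)


def read_panel(path, column_map: dict | None = None) -> LongitudinalDataset:
    """Read a header-ed CSV into a validated panel.

    ``column_map`` maps the canonical names (``subject``, ``time``,
    ``outcome`` and optionally ``offset``) to the file's column names; columns
    not mentioned are carried along as covariates under their own names.
    Rows with missing values in any mapped or covariate column are dropped
    with a logged count (ignorable missingness).
    """
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canon in ("subject", "time", "outcome", "offset"):
        src = column_map.get(canon, canon)
        if canon in ("subject", "time", "outcome") or src in raw.columns:
            if src not in raw.columns:
                raise ConfigurationError(
                    f"column {src!r} (for {canon!r}) not found in {list(raw.columns)}"
                )
            rename[src] = canon
    df = raw.rename(columns=rename)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(df))
    ds = LongitudinalDataset(df)
    logger.info(
        "read %d observations on %d subjects; zero fraction %.1f%%",
        ds.n_obs, ds.n_subjects, 100 * ds.zero_fraction,
    )
    return ds


def inter_visit_offsets(ds: LongitudinalDataset) -> LongitudinalDataset:
    """Set offsets to inter-visit gaps t_ij - t_{i,j-1}, with t_{i0} = 0.

    The count-increment convention: observation j covers (t_{i,j-1}, t_ij].
    """
    df = ds.df.copy()
    t = df["time"].to_numpy(dtype=float)
    prev = np.empty_like(t)
    codes = ds.subject_codes
    first = np.ones(len(t), dtype=bool)
    first[1:] = codes[1:] != codes[:-1]
    prev[first] = 0.0
    prev[~first] = t[:-1][~first[1:]]
    gaps = t - prev
    if np.any(gaps <= 0):
        i = int(np.argmax(gaps <= 0))
        raise ValidationError(
            f"nonpositive inter-visit gap for subject {df['subject'].iloc[i]} at time {t[i]}"
        )
    df["offset"] = gaps
    return LongitudinalDataset(df)


@dataclass(frozen=True)
class DesignMatrices:
    """Per-part design matrices with an intercept column first.

    The binary-part and intensity-part matrices are built independently and
    may (but need not) coincide.
    """

    X_binary: np.ndarray
    X_intensity: np.ndarray
    log_offset: np.ndarray
    binary_names: tuple
    intensity_names: tuple

    @property
    def q(self) -> int:
        return self.X_binary.shape[1]

    @property
    def p(self) -> int:
        return self.X_intensity.shape[1]


def _one_part(df: pd.DataFrame, terms, interactions, intercept: bool):
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for t in terms:
        if t not in df.columns:
            raise ConfigurationError(f"unknown term {t!r}")
        cols.append(df[t].to_numpy(dtype=float))
        names.append(t)
    for a, b in interactions:
        for t in (a, b):
            if t not in df.columns:
                raise ConfigurationError(f"unknown interaction term {t!r}")
        cols.append(df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), tuple(names)


def build_designs(
    ds: LongitudinalDataset,
    binary_terms=(),
    intensity_terms=(),
    interactions=(),
    intercept: bool = True,
) -> DesignMatrices:
    """Build the two design matrices: intercept, main effects, then products.

    ``interactions`` is a list of (a, b) column-name pairs whose product is
    appended to both parts.
    """
    Xb, nb = _one_part(ds.df, binary_terms, interactions, intercept)
    Xc, nc = _one_part(ds.df, intensity_terms, interactions, intercept)
    return DesignMatrices(
        X_binary=Xb,
        X_intensity=Xc,
        log_offset=np.log(ds.offset),
        binary_names=nb,
        intensity_names=nc,
    )
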