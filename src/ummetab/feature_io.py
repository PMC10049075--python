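"""Data model and delimited-text I/O for untargeted LC-MS feature data.

The central object is the :class:`FeatureTable`: a features x samples
abundance matrix with per-feature mass-to-charge (m/z), retention time and
ionisation polarity. Positive- and negative-mode acquisitions live in
separate tables and are analysed independently throughout the package,
because a metabolite may ionise in only one polarity.

Abundances move through three states: ``raw`` (non-negative intensities,
zeros meaning below detection), ``log1`` (natural ``log(1 + x)``) and ``z``
(per-feature standardised). State transitions are one-way; the state is
recorded on the table and checked by every stage.

On disk everything is TSV (features as rows, one column per sample), which
keeps diffs readable and round-trips exactly at 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ION_MODES = ("positive", "negative")
TRANSFORM_STATES = ("raw", "log1", "z")

GROUPS = ("UM", "control")
SUBCLASSES = ("BAP1", "SF3B1", "EIF1AX", "control")
PRIMARY_DRIVERS = ("GNAQ", "GNA11", "CYSLTR2", "missing")
BATCHES = ("discovery", "replication")
METASTASIS = ("yes", "no", "unknown")

_FLOAT_FMT = "%.12g"

METADATA_COLUMNS = [
    "sample_id",
    "group",
    "subclass",
    "primary_driver",
    "batch",
    "role",
    "storage_time",
    "age",
    "sex",
    "ltd",
    "metastasis",
]


class SchemaError(ValueError):
    """Structural mismatch between files/objects (e.g. unmatched sample sets)."""


class ValidationError(ValueError):
    """A domain invariant is violated (e.g. negative raw abundance)."""


class StateError(ValueError):
    """Operation applied to a table in the wrong transform state."""


class ConfigurationError(ValueError):
    """Invalid parameter or task configuration."""


class DegenerateDataError(ValueError):
    """Input carries no usable signal (e.g. an empty non-zero pool)."""


@dataclass
class FeatureTable:
    """Feature x sample abundance matrix for one ionisation mode.

    Parameters
    ----------
    feature_ids
        Unique opaque feature identifiers (row labels).
    mz
        Mass-to-charge ratio per feature (Th).
    rt
        Retention time per feature (seconds).
    ion_mode
        ``"positive"`` or ``"negative"``; one mode per table.
    abundances
        ``(n_features, n_samples)`` float matrix. In ``raw`` state all
        entries are >= 0 and 0 encodes below-detection.
    sample_ids
        Unique sample identifiers (column labels).
    transform_state
        One of ``raw``, ``log1``, ``z``.
    """

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray
    ion_mode: str
    abundances: np.ndarray
    sample_ids: list[str]
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            self.abundances = self.abundances.reshape(
                len(self.feature_ids), len(self.sample_ids)
            )
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.ion_mode not in ION_MODES:
            raise ValidationError(f"unknown ion mode {self.ion_mode!r}")
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform state {self.transform_state!r}")
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.abundances.shape != (nf, ns):
            raise SchemaError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{nf} features x {ns} samples"
            )
        if self.mz.shape != (nf,) or self.rt.shape != (nf,):
            raise SchemaError("mz/rt must have one entry per feature")
        if len(set(self.feature_ids)) != nf:
            raise ValidationError("feature_ids are not unique")
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("sample_ids are not unique")
        if np.isnan(self.abundances).any():
            raise ValidationError("abundance matrix contains missing cells")
        if self.transform_state == "raw" and nf and ns:
            if self.abundances.min() < 0:
                raise ValidationError("raw abundances must be non-negative")

    # -- convenience -----------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            ion_mode=self.ion_mode,
            abundances=self.abundances.copy(),
            sample_ids=list(self.sample_ids),
            transform_state=self.transform_state,
        )

    def with_state(self, abundances: np.ndarray, state: str) -> "FeatureTable":
        """New table with the same axes but different values/state."""
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            ion_mode=self.ion_mode,
            abundances=abundances,
            sample_ids=list(self.sample_ids),
            transform_state=state,
        )

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def select_features(self, keep: Iterable[str] | np.ndarray) -> "FeatureTable":
        """Subset rows, preserving order. ``keep`` is a boolean mask or ids."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([f in wanted for f in self.feature_ids])
        idx = np.flatnonzero(mask)
        return FeatureTable(
            feature_ids=[self.feature_ids[i] for i in idx],
            mz=self.mz[idx],
            rt=self.rt[idx],
            ion_mode=self.ion_mode,
            abundances=self.abundances[idx, :],
            sample_ids=list(self.sample_ids),
            transform_state=self.transform_state,
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Subset columns in the given order."""
        wanted = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise SchemaError(f"samples not in table: {missing}")
        idx = [pos[s] for s in wanted]
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            ion_mode=self.ion_mode,
            abundances=self.abundances[:, idx],
            sample_ids=wanted,
            transform_state=self.transform_state,
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations driving stratification and supervision.

    Wraps a DataFrame indexed by ``sample_id`` with the columns listed in
    :data:`METADATA_COLUMNS`. ``role`` is ``study``, ``qc``, ``blank`` or
    ``replicate_of:<sample_id>``; ``ltd`` (longest tumor diameter, mm) is
    NaN for controls; ``storage_time`` and ``age`` are in years.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise SchemaError("metadata needs a sample_id column")
        self.frame = df
        self.validate()

    def validate(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        for col in METADATA_COLUMNS[1:]:
            if col not in df.columns:
                raise SchemaError(f"metadata missing column {col!r}")
        bad = df.loc[~df["group"].isin(GROUPS)].index.tolist()
        if bad:
            raise ValidationError(f"unknown group for samples {bad}")
        bad = df.loc[~df["subclass"].isin(SUBCLASSES)].index.tolist()
        if bad:
            raise ValidationError(f"unknown subclass for samples {bad}")
        bad = df.loc[~df["batch"].isin(BATCHES)].index.tolist()
        if bad:
            raise ValidationError(f"unknown batch for samples {bad}")
        ok_role = df["role"].isin(["study", "qc", "blank"]) | df[
            "role"
        ].str.startswith("replicate_of:")
        if (~ok_role).any():
            raise ValidationError(
                f"unknown role for samples {df.index[~ok_role].tolist()}"
            )
        mismatch = (df["subclass"] == "control") != (df["group"] == "control")
        if mismatch.any():
            raise ValidationError(
                "subclass is 'control' iff group is 'control'; violated by "
                f"{df.index[mismatch].tolist()}"
            )
        ltd = pd.to_numeric(df["ltd"], errors="coerce")
        bad_ltd = ltd.notna() & (ltd <= 0)
        if bad_ltd.any():
            raise ValidationError(
                f"ltd must be > 0 when present: {df.index[bad_ltd].tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def column(self, name: str, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.frame.loc[ids, name].to_numpy()

    def study_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["role"] == "study"])

    def qc_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["role"] == "qc"])


@dataclass(frozen=True)
class StandardSet:
    """Feature ids of spiked internal/external standards.

    Internal standards anchor the PC-regression normalization; external
    standards are carried as an independent check set. The two sets are
    disjoint and at least two internal standards are required (their
    principal components are two-dimensional).
    """

    internal: frozenset[str]
    external: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "internal", frozenset(self.internal))
        object.__setattr__(self, "external", frozenset(self.external))
        if self.internal & self.external:
            raise ValidationError("internal and external standards overlap")
        if len(self.internal) < 2:
            raise ConfigurationError("need at least 2 internal standards")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.internal | self.external

    def check_in_table(self, table: FeatureTable) -> None:
        missing = self.all_ids - set(table.feature_ids)
        if missing:
            raise SchemaError(f"standards missing from table: {sorted(missing)}")


@dataclass
class PipelineConfig:
    """Analysis parameters. Defaults are the protocol constants used
    throughout: 2nd-percentile detection threshold with >= 5 samples above
    it, 75% non-zero eligibility with |Z| > 3 outlier exclusion for the
    normalization fit, oversampling to 200 per class, N(0, 0.25) training
    noise, a 150-tree depth-100 random forest, 25 AUC bootstraps, and ten
    50%-subsample repeats."""

    master_seed: int = 0
    oversample_n: int = 200
    noise_sd: float = 0.25
    n_trees: int = 150
    max_depth: int = 100
    n_boot: int = 25
    n_repeats: int = 10
    subsample_frac: float = 0.5
    min_samples_above: int = 5
    pooled_percentile: float = 2.0
    nonzero_frac: float = 0.75
    z_outlier: float = 3.0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.subsample_frac <= 1:
            raise ConfigurationError("subsample_frac must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name in ("oversample_n", "n_trees", "max_depth", "n_boot", "n_repeats"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Readers / writers


def write_feature_table(
    table: FeatureTable,
    meta: SampleMetadata,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> Path:
    """Write a table (and optionally its metadata) as TSV.

    Sample columns are sorted by sample id so repeated writes of the same
    table are byte-identical. Values are serialised with 12 significant
    digits.
    """
    path = Path(path)
    _check_sample_match(table.sample_ids, meta.sample_ids)
    order = sorted(table.sample_ids)
    tbl = table.select_samples(order)
    df = pd.concat(
        [
            pd.DataFrame(
                {
                    "feature_id": tbl.feature_ids,
                    "mz": tbl.mz,
                    "rt": tbl.rt,
                    "ion_mode": tbl.ion_mode,
                }
            ),
            pd.DataFrame(tbl.abundances, columns=order),
        ],
        axis=1,
    )
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# transform_state={table.transform_state}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    if metadata_path is not None:
        write_sample_metadata(meta, metadata_path)
    return path


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    df = meta.frame.sort_index().reset_index()[METADATA_COLUMNS]
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_feature_table(
    path: str | Path, metadata_path: str | Path
) -> tuple[FeatureTable, SampleMetadata]:
    """Read a TSV feature table plus its sample metadata and cross-validate."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        state = "raw"
        if first.startswith("#"):
            state = first.split("=", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    required = ["feature_id", "mz", "rt", "ion_mode"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"feature table missing columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in required]
    modes = set(df["ion_mode"].astype(str)) if len(df) else set()
    if len(modes) > 1:
        raise ValidationError(f"mixed ion modes in one table: {sorted(modes)}")
    ion_mode = modes.pop() if modes else "positive"
    meta = read_sample_metadata(metadata_path)
    _check_sample_match(sample_cols, meta.sample_ids)
    abundances = (
        df[sample_cols].to_numpy(dtype=float)
        if sample_cols
        else np.empty((len(df), 0))
    )
    table = FeatureTable(
        feature_ids=df["feature_id"].astype(str).tolist(),
        mz=df["mz"].to_numpy(dtype=float),
        rt=df["rt"].to_numpy(dtype=float),
        ion_mode=ion_mode,
        abundances=abundances,
        sample_ids=sample_cols,
        transform_state=state,
    )
    return table, meta


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("group", "subclass", "primary_driver", "batch", "role", "sex", "metastasis"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return SampleMetadata(df)


def write_standards(standards: StandardSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "internal": sorted(standards.internal),
        "external": sorted(standards.external),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_standards(path: str | Path) -> StandardSet:
    with open(path) as fh:
        payload = json.load(fh)
    return StandardSet(
        internal=frozenset(payload.get("internal", [])),
        external=frozenset(payload.get("external", [])),
    )


def _check_sample_match(table_samples: Iterable[str], meta_samples: Iterable[str]) -> None:
    t, m = set(table_samples), set(meta_samples)
    if t != m:
        only_t = sorted(t - m)
        only_m = sorted(m - t)
        raise SchemaError(
            f"sample sets differ: only in table {only_t}, only in metadata {only_m}"
        )
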