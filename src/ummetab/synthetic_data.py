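"""Synthetic plasma-metabolomics cohorts.

Patient-level LC-MS data from the uveal-melanoma study design this package
targets cannot be shared, so every stage is exercised on simulated cohorts
that reproduce the statistical structure the analysis assumes:

* two ionisation modes measured on the same samples;
* a discovery batch (37 BAP1 / 16 SF3B1 / 15 EIF1AX / 46 controls) and a
  replication batch (19 / 17 / 9, no controls), matching the default
  cohort composition;
* log-normal abundances: on the log scale each feature j in sample i is

  ``y_ij = mu_j + batch_ij + delta_j*[UM] + s_jg*[subclass g] + eps_ij``

  with ``eps_ij ~ N(0, sigma^2)``, exponentiated back to the raw scale;
* multiplicative batch effects whose distribution is shared between
  spiked standards and biological features (and, in ``share_exact`` mode,
  whose sample-level latent structure is shared exactly, so that
  regressing on the standards' principal components can remove it);
* below-detection dropout (zeros) on biological features, never on
  standards;
* pooled-plasma QC samples: low-noise replicates of the mean profile;
* a designated feature pair correlated with longest tumor diameter (LTD).

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_io import (
    ConfigurationError,
    FeatureTable,
    SampleMetadata,
    StandardSet,
    StateError,
    METADATA_COLUMNS,
)

#: default per-batch group sizes (discovery / replication cohorts)
DEFAULT_DISCOVERY = {"control": 46, "BAP1": 37, "SF3B1": 16, "EIF1AX": 15}
DEFAULT_REPLICATION = {"control": 0, "BAP1": 19, "SF3B1": 17, "EIF1AX": 9}

_SUBCLASS_META_RISK = {"BAP1": 0.7, "SF3B1": 0.4, "EIF1AX": 0.1}


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    ``effect_size`` is the log-scale mean shift of informative features in
    UM samples versus controls (so the per-feature Cohen's d is
    ``effect_size / feature_noise_sd``); ``subclass_effect`` scales
    additional random per-subclass shifts on the informative features
    (0 means the three molecular subclasses are indistinguishable);
    ``batch_effect_sd`` is the spread of per-feature multiplicative batch
    offsets applied to the replication batch, on the log scale, shared in
    distribution with the standards. With ``share_exact`` the batch/drift
    variation of features and standards loads on the same two sample-level
    latent factors, which is the positive control for PC-regression
    normalization.
    """

    n_discovery: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DISCOVERY))
    n_replication: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATION)
    )
    n_features: int = 200
    n_informative: int = 40
    effect_size: float = 1.0
    subclass_effect: float = 0.0
    batch_effect_sd: float = 0.5
    feature_noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    dropout_rate: float = 0.05
    n_qc: int = 3
    n_internal: int = 10
    n_external: int = 7
    ltd_feature_corr: float = 0.0
    share_exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal < 2:
            raise ConfigurationError("need at least 2 internal standards")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative exceeds n_features")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        for d in (self.n_discovery, self.n_replication):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("group counts must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated cohort (one per mode)."""

    informative_ids: dict[str, list[str]]
    batch_offsets: dict[str, dict[str, float]]  # mode -> feature_id -> offset
    ltd_feature_ids: dict[str, list[str]]
    group_effects: dict[str, dict[str, float]]


def share_exact_stress_config(
    seed: int, batch_effect_sd: float = 1.0, n_features: int = 120
) -> SimulationConfig:
    """Positive-control cohort for PC-regression normalization.

    Technical variation of features and standards loads on the same two
    sample-level latent factors (``share_exact``), with no group effects
    and no dropout, so the batch component is exactly the kind of
    variation the standards' principal components can express. Removal of
    batch-mean differences on this input measures the normalization's
    recovery in isolation; below-detection dropout is a separate
    phenomenon exercised elsewhere.
    """
    return SimulationConfig(
        n_features=n_features,
        n_informative=0,
        effect_size=0.0,
        subclass_effect=0.0,
        batch_effect_sd=batch_effect_sd,
        dropout_rate=0.0,
        share_exact=True,
        seed=seed,
    )


def simulate_cohort(
    cfg: SimulationConfig, return_truth: bool = False
) -> tuple[FeatureTable, FeatureTable, SampleMetadata, StandardSet]:
    """Generate positive- and negative-mode raw tables over one cohort.

    Returns ``(pos_table, neg_table, metadata, standards)``; with
    ``return_truth=True`` a :class:`SimulationTruth` is appended. Standard
    features carry the same ids in both modes (they are the same spiked
    compounds measured twice), so one :class:`StandardSet` applies to both
    tables.
    """
    root = np.random.SeedSequence(cfg.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    meta = _simulate_metadata(cfg, meta_rng)

    std_ids_int = [f"IS{k+1:02d}" for k in range(cfg.n_internal)]
    std_ids_ext = [f"ES{k+1:02d}" for k in range(cfg.n_external)]
    standards = StandardSet(internal=frozenset(std_ids_int), external=frozenset(std_ids_ext))

    mode_seqs = root.spawn(3)[1:]
    tables = {}
    truth = SimulationTruth(
        informative_ids={}, batch_offsets={}, ltd_feature_ids={}, group_effects={}
    )
    for mode, seq in zip(("positive", "negative"), mode_seqs):
        tables[mode] = _simulate_mode(
            cfg, meta, std_ids_int, std_ids_ext, mode, np.random.default_rng(seq), truth
        )
    if return_truth:
        return tables["positive"], tables["negative"], meta, standards, truth
    return tables["positive"], tables["negative"], meta, standards


def _simulate_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    counter = 0
    for batch, sizes, prefix in (
        ("discovery", cfg.n_discovery, "D"),
        ("replication", cfg.n_replication, "R"),
    ):
        for subclass in ("control", "BAP1", "SF3B1", "EIF1AX"):
            for _ in range(sizes.get(subclass, 0)):
                counter += 1
                sid = f"{prefix}{counter:03d}"
                is_um = subclass != "control"
                rows.append(
                    {
                        "sample_id": sid,
                        "group": "UM" if is_um else "control",
                        "subclass": subclass,
                        "primary_driver": (
                            rng.choice(
                                ["GNAQ", "GNA11", "CYSLTR2", "missing"],
                                p=[0.38, 0.42, 0.02, 0.18],
                            )
                            if is_um
                            else "missing"
                        ),
                        "batch": batch,
                        "role": "study",
                        "storage_time": float(
                            np.round(rng.uniform(0, 20) if is_um else rng.uniform(3, 5), 2)
                        ),
                        "age": float(
                            np.round(
                                rng.normal(63.0, 12.0) if is_um else rng.normal(73.9, 8.0), 1
                            )
                        ),
                        "sex": str(rng.choice(["M", "F"])),
                        "ltd": (
                            float(np.round(max(rng.normal(13.5, 3.2), 3.0), 1))
                            if is_um
                            else np.nan
                        ),
                        "metastasis": (
                            ("yes" if rng.random() < _SUBCLASS_META_RISK[subclass] else "no")
                            if is_um
                            else "unknown"
                        ),
                    }
                )
        for q in range(cfg.n_qc):
            counter += 1
            rows.append(
                {
                    "sample_id": f"{prefix}{counter:03d}-QC{q+1}",
                    "group": "control",
                    "subclass": "control",
                    "primary_driver": "missing",
                    "batch": batch,
                    "role": "qc",
                    "storage_time": 0.0,
                    "age": np.nan,
                    "sex": "M",
                    "ltd": np.nan,
                    "metastasis": "unknown",
                }
            )
    frame = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return SampleMetadata(frame)


def _simulate_mode(
    cfg: SimulationConfig,
    meta: SampleMetadata,
    std_ids_int: list[str],
    std_ids_ext: list[str],
    mode: str,
    rng: np.random.Generator,
    truth: SimulationTruth,
) -> FeatureTable:
    prefix = "P" if mode == "positive" else "N"
    feat_ids = [f"{prefix}{j+1:04d}" for j in range(cfg.n_features)]
    std_ids = std_ids_int + std_ids_ext
    all_ids = std_ids + feat_ids
    n_std = len(std_ids)
    n_all = n_std + cfg.n_features

    sample_ids = meta.sample_ids
    n = len(sample_ids)
    df = meta.frame
    is_repl = (df["batch"].to_numpy() == "replication").astype(float)
    is_um = (df["group"].to_numpy() == "UM").astype(float)
    is_qc = df["role"].to_numpy() == "qc"
    subclass = df["subclass"].to_numpy()

    mu = np.concatenate(
        [
            rng.normal(cfg.baseline_mean, 0.5, size=n_std),  # spiked at fixed conc.
            rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_features),
        ]
    )
    sigma = np.full(n_all, cfg.feature_noise_sd)
    sigma[:n_std] = 0.05  # standards: instrument noise only
    informative = np.zeros(n_all, dtype=bool)
    inf_idx = n_std + rng.choice(cfg.n_features, size=cfg.n_informative, replace=False)
    informative[inf_idx] = True
    delta = np.where(informative, cfg.effect_size, 0.0)

    # per-subclass shifts on informative features only
    sub_shift = {
        g: np.where(informative, rng.normal(0.0, 1.0, size=n_all) * cfg.subclass_effect, 0.0)
        for g in ("BAP1", "SF3B1", "EIF1AX")
    }

    # --- technical (batch) structure -----------------------------------
    if cfg.share_exact:
        # two latent sample factors; batch shows up as a factor-1 mean shift
        z1 = is_repl * 1.0 + rng.normal(0.0, 0.3, size=n)
        z2 = is_repl * 0.3 + rng.normal(0.0, 0.3, size=n)
        load1 = rng.normal(0.0, cfg.batch_effect_sd, size=n_all)
        load2 = rng.normal(0.0, 0.3 * cfg.batch_effect_sd, size=n_all)
        technical = np.outer(load1, z1) + np.outer(load2, z2)
        batch_offset = load1 * 1.0 + load2 * 0.3  # expected batch-mean shift
    else:
        b = rng.normal(0.0, cfg.batch_effect_sd, size=n_all)
        technical = np.outer(b, is_repl)
        batch_offset = b

    # --- assemble log-scale matrix --------------------------------------
    y = np.tile(mu[:, None], (1, n)) + technical
    y += np.outer(delta, is_um)
    for g, shift in sub_shift.items():
        y += np.outer(shift, (subclass == g).astype(float))
    eps = rng.normal(0.0, 1.0, size=(n_all, n)) * sigma[:, None]
    # QC samples are pooled-plasma replicates: no biology, low noise
    y[:, is_qc] = np.tile(mu[:, None], (1, int(is_qc.sum()))) + technical[:, is_qc]
    eps[:, is_qc] = rng.normal(0.0, 0.1, size=(n_all, int(is_qc.sum())))
    y += eps

    # --- LTD-correlated feature pair ------------------------------------
    ltd_ids: list[str] = []
    if cfg.ltd_feature_corr != 0.0:
        um_mask = (is_um > 0) & ~is_qc
        ltd = pd.to_numeric(df["ltd"], errors="coerce").to_numpy()[um_mask]
        ltd_z = (ltd - ltd.mean()) / ltd.std()
        r = cfg.ltd_feature_corr
        for k in range(2):
            j = n_std + cfg.n_features - 1 - k  # last two features
            noise = rng.normal(0.0, 1.0, size=um_mask.sum())
            y[j, um_mask] = mu[j] + technical[j, um_mask] + sigma[j] * (
                r * ltd_z + np.sqrt(1 - r**2) * noise
            )
            ltd_ids.append(all_ids[j])

    raw = np.exp(y)

    # --- dropout (never on standards, never on QC) ----------------------
    if cfg.dropout_rate > 0:
        drop = rng.random(size=(n_all, n)) < cfg.dropout_rate
        drop[:n_std, :] = False
        drop[:, is_qc] = False
        raw[drop] = 0.0

    truth.informative_ids[mode] = [all_ids[j] for j in np.flatnonzero(informative)]
    truth.batch_offsets[mode] = dict(zip(all_ids, batch_offset.tolist()))
    truth.ltd_feature_ids[mode] = ltd_ids
    truth.group_effects[mode] = dict(zip(all_ids, delta.tolist()))

    return FeatureTable(
        feature_ids=all_ids,
        mz=np.round(rng.uniform(70.0, 1050.0, size=n_all), 4),
        rt=np.round(rng.uniform(30.0, 900.0, size=n_all), 1),
        ion_mode=mode,
        abundances=raw,
        sample_ids=sample_ids,
        transform_state="raw",
    )


def inject_batch_effect(
    table: FeatureTable,
    meta: SampleMetadata,
    sd: float,
    seed: int,
    return_offsets: bool = False,
) -> FeatureTable:
    """Add per-feature offsets ``b_j ~ N(0, sd^2)`` to replication samples.

    A stress input for normalization: applied on the ``log1`` scale to all
    features including standards. With ``return_offsets=True`` also
    returns the drawn offsets keyed by feature id.
    """
    if table.transform_state != "log1":
        raise StateError("inject_batch_effect expects a log1-state table")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sd, size=table.n_features)
    is_repl = meta.column("batch", table.sample_ids) == "replication"
    out = table.abundances + np.outer(b, is_repl.astype(float))
    new = table.with_state(out, "log1")
    if return_offsets:
        return new, dict(zip(table.feature_ids, b.tolist()))
    return new
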