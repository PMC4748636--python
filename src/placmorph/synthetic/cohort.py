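"""Condition-structured cohorts of per-sample morphometric indices.

Indices are positive and right-skewed in real cohorts, so each condition
draws every index from a log-normal distribution parameterised by a median
(the location ``exp(mu)``) and a log-scale dispersion ``sigma``.  The default
cohort mirrors the study design this package emulates: healthy term live
births as the control arm plus preterm births and stillbirth groups (cord
accident, diabetes, hypertension, infection, FGR, unknown cause), with
effect *directions* for FGR -- more SNAs, less proliferation, fewer vessels
per villus, more avascular villi, greater trophoblast area, fewer
leukocytes -- and paired pre/post perfusion arms.  Effect magnitudes are
simulation choices (the source study prints directions, not raw values) and
are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..errors import ConfigError

#: Canonical cohort-table schema (order matters for CSV round trips).
INDEX_COLUMNS = (
    "sna_per_mm2",
    "proliferative_index",
    "vessels_per_villus",
    "avascular_pct",
    "trophoblast_fraction",
    "cd45_per_1000",
)
COHORT_COLUMNS = ("sample_id", "condition") + INDEX_COLUMNS

#: Control-arm medians (healthy term live births) and log-scale dispersions.
CONTROL_MEDIANS = {
    "sna_per_mm2": 15.0,
    "proliferative_index": 0.05,
    "vessels_per_villus": 4.0,
    "avascular_pct": 5.0,
    "trophoblast_fraction": 0.28,
    "cd45_per_1000": 10.0,
}
CONTROL_SIGMAS = {
    "sna_per_mm2": 0.30,
    "proliferative_index": 0.30,
    "vessels_per_villus": 0.25,
    "avascular_pct": 0.45,
    "trophoblast_fraction": 0.18,
    "cd45_per_1000": 0.40,
}

#: Median ratios versus control encoding the reported effect directions.
#: 1.0 = no shift.  Magnitudes are generator choices.
CONDITION_EFFECTS: dict[str, dict[str, float]] = {
    "control": {},
    "preterm": {"sna_per_mm2": 0.7, "vessels_per_villus": 1.3, "avascular_pct": 0.5},
    "cord_accident": {
        "sna_per_mm2": 1.7,
        "proliferative_index": 0.45,
        "avascular_pct": 2.0,
    },
    "diabetes": {},
    "hypertension": {
        "sna_per_mm2": 1.7,
        "proliferative_index": 0.7,
        "avascular_pct": 2.0,
        "cd45_per_1000": 0.55,
    },
    "infection": {"proliferative_index": 0.8, "trophoblast_fraction": 1.35},
    "fgr": {
        "sna_per_mm2": 2.0,
        "proliferative_index": 0.5,
        "vessels_per_villus": 0.6,
        "avascular_pct": 3.0,
        "trophoblast_fraction": 1.4,
        "cd45_per_1000": 0.5,
    },
    "unknown": {
        "sna_per_mm2": 1.6,
        "proliferative_index": 0.75,
        "vessels_per_villus": 0.65,
        "avascular_pct": 2.2,
    },
}

#: Group sizes of the emulated study arms.
CONDITION_N = {
    "control": 10,
    "preterm": 7,
    "cord_accident": 8,
    "diabetes": 5,
    "hypertension": 8,
    "infection": 8,
    "fgr": 10,
    "unknown": 10,
}


@dataclass(frozen=True)
class ConditionSpec:
    """One cohort arm: per-index log-normal medians and dispersions."""

    label: str
    n_samples: int
    medians: dict[str, float]
    sigmas: dict[str, float]
    paired_with: str | None = None
    pairing_sigma: float = 0.15  # residual log-scale noise between paired arms

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"condition {self.label!r}: n_samples must be >= 1")
        for idx in INDEX_COLUMNS:
            m = self.medians.get(idx)
            s = self.sigmas.get(idx)
            if m is None or s is None:
                raise ConfigError(f"condition {self.label!r}: missing index {idx!r}")
            if not (np.isfinite(m) and m > 0):
                raise ConfigError(
                    f"condition {self.label!r}: median for {idx!r} must be finite > 0"
                )
            if not (np.isfinite(s) and s > 0):
                raise ConfigError(
                    f"condition {self.label!r}: sigma for {idx!r} must be finite > 0"
                )


@dataclass(frozen=True)
class CohortConfig:
    conditions: tuple[ConditionSpec, ...]

    def validate(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate condition labels")
        by_label = {c.label: c for c in self.conditions}
        for c in self.conditions:
            c.validate()
            if c.paired_with is not None:
                partner = by_label.get(c.paired_with)
                if partner is None:
                    raise ConfigError(
                        f"condition {c.label!r} paired with unknown {c.paired_with!r}"
                    )
                if partner.n_samples != c.n_samples:
                    raise ConfigError(
                        f"paired conditions {c.label!r}/{c.paired_with!r} must have "
                        "equal n_samples"
                    )


def condition_spec(
    label: str,
    n_samples: int,
    effects: dict[str, float] | None = None,
    sigma_overrides: dict[str, float] | None = None,
    paired_with: str | None = None,
) -> ConditionSpec:
    """Build a ConditionSpec from median *ratios* against the control arm."""
    effects = effects or {}
    medians = {
        idx: CONTROL_MEDIANS[idx] * effects.get(idx, 1.0) for idx in INDEX_COLUMNS
    }
    sigmas = dict(CONTROL_SIGMAS)
    if sigma_overrides:
        sigmas.update(sigma_overrides)
    return ConditionSpec(label, n_samples, medians, sigmas, paired_with=paired_with)


def default_cohort_config(include_perfusion: bool = False) -> CohortConfig:
    """The emulated study's cohort structure at the default effect sizes."""
    conditions = [
        condition_spec(label, CONDITION_N[label], CONDITION_EFFECTS[label])
        for label in CONDITION_N
    ]
    # leukocyte counts in infection span a wide range
    conditions = [
        replace(c, sigmas={**c.sigmas, "cd45_per_1000": 0.9})
        if c.label == "infection"
        else c
        for c in conditions
    ]
    if include_perfusion:
        conditions.append(condition_spec("perfusion_pre", 7))
        conditions.append(
            condition_spec(
                "perfusion_post",
                7,
                {"sna_per_mm2": 0.7, "cd45_per_1000": 0.8},
                paired_with="perfusion_pre",
            )
        )
    return CohortConfig(tuple(conditions))


def simulate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw one cohort table: one row per sample, six indices per row.

    Paired conditions share sample ids with their partner and are generated
    from the partner's log-values plus the configured median shift and a
    small pairing residual, giving positively correlated pairs.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_label = {c.label: c for c in config.conditions}
    log_values: dict[str, np.ndarray] = {}
    rows: list[dict] = []

    # generate unpaired arms first so a paired arm can reference its partner
    ordered = [c for c in config.conditions if c.paired_with is None] + [
        c for c in config.conditions if c.paired_with is not None
    ]
    sample_ids: dict[str, list[str]] = {}
    for c in ordered:
        n = c.n_samples
        mu = np.log([c.medians[idx] for idx in INDEX_COLUMNS])
        sigma = np.array([c.sigmas[idx] for idx in INDEX_COLUMNS])
        if c.paired_with is None:
            logs = mu + sigma * rng.standard_normal((n, len(INDEX_COLUMNS)))
            ids = [f"{c.label}_{i + 1:02d}" for i in range(n)]
        else:
            partner = by_label[c.paired_with]
            mu_p = np.log([partner.medians[idx] for idx in INDEX_COLUMNS])
            logs = (
                log_values[c.paired_with]
                + (mu - mu_p)
                + c.pairing_sigma * rng.standard_normal((n, len(INDEX_COLUMNS)))
            )
            ids = sample_ids[c.paired_with]
        log_values[c.label] = logs
        sample_ids[c.label] = ids
        values = np.exp(logs)
        # keep the two fractions physically valid
        col = INDEX_COLUMNS.index("proliferative_index")
        values[:, col] = np.minimum(values[:, col], 1.0)
        col = INDEX_COLUMNS.index("trophoblast_fraction")
        values[:, col] = np.minimum(values[:, col], 0.95)
        col = INDEX_COLUMNS.index("avascular_pct")
        values[:, col] = np.minimum(values[:, col], 100.0)
        for i in range(n):
            row = {"sample_id": ids[i], "condition": c.label}
            row.update(dict(zip(INDEX_COLUMNS, values[i])))
            rows.append(row)

    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return df
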