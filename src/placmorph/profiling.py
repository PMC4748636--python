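"""Morphometric phenotype profiling against an FGR reference pattern.

Each sample's six indices are classified as HIGH / LOW / UNCHANGED relative
to the healthy-control cohort, and the resulting profile is matched against
the characteristic FGR pattern (more SNAs, less proliferation, fewer vessels
per villus, more avascular villi, greater trophoblast area, fewer
leukocytes).  A sample is "similar to FGR" when every *required* feature of
the reference matches; the leukocyte feature is advisory, because the
published unknown-cause profiles that are similar to FGR show unchanged
leukocyte counts.

No universally agreed criterion exists for assigning High/Low/Unchanged to
a single sample against a small control group; the default here is the
control-range rule (outside the observed control range), with a percentile
rule available.  The rule in force is recorded in all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError

FEATURES = (
    "snas",
    "proliferation",
    "vascularity",
    "avascular",
    "trophoblast",
    "leukocytes",
)

#: Which index column feeds each profile feature.
FEATURE_INDEX = {
    "snas": "sna_per_mm2",
    "proliferation": "proliferative_index",
    "vascularity": "vessels_per_villus",
    "avascular": "avascular_pct",
    "trophoblast": "trophoblast_fraction",
    "leukocytes": "cd45_per_1000",
}


class FeatureLevel(str, Enum):
    HIGH = "High"
    LOW = "Low"
    UNCHANGED = "Unchanged"


@dataclass(frozen=True)
class MorphometricProfile:
    """Per-feature HIGH/LOW/UNCHANGED levels for one sample."""

    sample_id: str
    levels: dict[str, FeatureLevel]

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.levels)
        if missing:
            raise ConfigError(f"profile {self.sample_id!r} missing features {sorted(missing)}")

    def __getitem__(self, feature: str) -> FeatureLevel:
        return self.levels[feature]


@dataclass(frozen=True)
class ReferenceProfile:
    """Expected level per feature plus the set of features that must match."""

    levels: dict[str, FeatureLevel]
    required: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required:
            raise ConfigError("reference profile needs at least one required feature")
        unknown = set(self.required) - set(self.levels)
        if unknown:
            raise ConfigError(f"required features without levels: {sorted(unknown)}")


@dataclass(frozen=True)
class MatchResult:
    sample_id: str
    agreement: dict[str, bool]
    n_matched: int
    similar: bool

    @property
    def verdict(self) -> str:
        return "Similar to FGR" if self.similar else "Not similar"


def fgr_reference() -> ReferenceProfile:
    """The FGR morphometric pattern used as the similarity reference.

    Required features: SNAs High, proliferation Low, vascularity Low,
    avascular villi High, trophoblast High.  Leukocytes Low is part of the
    FGR pattern but advisory only (see module docstring).
    """
    return ReferenceProfile(
        levels={
            "snas": FeatureLevel.HIGH,
            "proliferation": FeatureLevel.LOW,
            "vascularity": FeatureLevel.LOW,
            "avascular": FeatureLevel.HIGH,
            "trophoblast": FeatureLevel.HIGH,
            "leukocytes": FeatureLevel.LOW,
        },
        required=frozenset(
            {"snas", "proliferation", "vascularity", "avascular", "trophoblast"}
        ),
    )


def classify_feature_level(
    sample_value: float,
    control_values: np.ndarray,
    rule: str = "range",
    percentile: float = 5.0,
) -> FeatureLevel:
    """Classify one index value against the control cohort.

    ``rule="range"`` (default): HIGH if above every control value, LOW if
    below every control value, else UNCHANGED.  ``rule="percentile"``: HIGH /
    LOW outside the [percentile, 100-percentile] control band.
    """
    if not np.isfinite(sample_value):
        raise ConfigError("sample value must be finite")
    control = np.asarray(control_values, dtype=float)
    if control.size < 3:
        raise ConfigError("need >= 3 control values to classify a level")
    if rule == "range":
        lo, hi = control.min(), control.max()
    elif rule == "percentile":
        lo, hi = np.percentile(control, [percentile, 100.0 - percentile])
    else:
        raise ConfigError(f"unknown level rule {rule!r}")
    if sample_value > hi:
        return FeatureLevel.HIGH
    if sample_value < lo:
        return FeatureLevel.LOW
    return FeatureLevel.UNCHANGED


def build_profile(
    sample: pd.Series | dict,
    controls: pd.DataFrame,
    rule: str = "range",
    percentile: float = 5.0,
) -> MorphometricProfile:
    """Profile one sample's six indices against a control cohort table."""
    levels = {}
    for feature, column in FEATURE_INDEX.items():
        if column not in controls.columns:
            raise ConfigError(f"control table missing index column {column!r}")
        try:
            value = float(sample[column])
        except (KeyError, TypeError):
            raise ConfigError(f"sample missing index {column!r}") from None
        levels[feature] = classify_feature_level(
            value, controls[column].to_numpy(), rule=rule, percentile=percentile
        )
    sample_id = str(sample.get("sample_id", "sample"))
    return MorphometricProfile(sample_id=sample_id, levels=levels)


def match_profile(profile: MorphometricProfile, ref: ReferenceProfile) -> MatchResult:
    """Verdict: similar iff every required reference feature matches."""
    agreement = {
        f: profile.levels[f] == ref.levels[f] for f in FEATURES if f in ref.levels
    }
    similar = all(agreement[f] for f in ref.required)
    return MatchResult(
        sample_id=profile.sample_id,
        agreement=agreement,
        n_matched=sum(agreement.values()),
        similar=similar,
    )


def profile_cohort(
    samples: pd.DataFrame,
    controls: pd.DataFrame,
    ref: ReferenceProfile | None = None,
    rule: str = "range",
) -> tuple[pd.DataFrame, int]:
    """Profile every sample row and count "similar" verdicts.

    Returns a table with one row per sample (feature levels, verdict,
    n_matched) and the similarity count.
    """
    if ref is None:
        ref = fgr_reference()
    rows = []
    n_similar = 0
    for _, sample in samples.iterrows():
        profile = build_profile(sample, controls, rule=rule)
        result = match_profile(profile, ref)
        n_similar += result.similar
        row = {"sample_id": profile.sample_id}
        row.update({f: profile.levels[f].value for f in FEATURES})
        row["verdict"] = result.verdict
        row["n_matched"] = result.n_matched
        rows.append(row)
    columns = ["sample_id", *FEATURES, "verdict", "n_matched"]
    return pd.DataFrame(rows, columns=columns), n_similar


def match_profiles(
    profiles: list[MorphometricProfile], ref: ReferenceProfile | None = None
) -> tuple[list[MatchResult], int]:
    """Match pre-built profiles (e.g. a transcribed fixture) against a reference."""
    if ref is None:
        ref = fgr_reference()
    results = [match_profile(p, ref) for p in profiles]
    return results, sum(r.similar for r in results)


def consistent_required_sets(
    profiles: list[MorphometricProfile],
    verdicts: list[bool],
    levels: dict[str, FeatureLevel] | None = None,
) -> list[frozenset[str]]:
    """All required-feature subsets that reproduce the given verdicts.

    Brute force over every subset of the six features: a subset is
    consistent when "all required features match ``levels``" equals the
    recorded verdict for every profile.  Used to audit the choice of
    required set against transcribed published verdicts; more than one
    consistent subset may exist.
    """
    if levels is None:
        levels = fgr_reference().levels
    out = []
    for r in range(len(FEATURES) + 1):
        for subset in combinations(FEATURES, r):
            if not subset:
                # empty required set says everything is similar
                if all(verdicts):
                    out.append(frozenset())
                continue
            ok = all(
                all(p.levels[f] == levels[f] for f in subset) == v
                for p, v in zip(profiles, verdicts)
            )
            if ok:
                out.append(frozenset(subset))
    return out
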