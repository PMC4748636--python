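"""Transcribed feature-level profiles of the ten unknown-cause stillbirths.

Static fixture: per-feature High/Low/Unchanged levels and the printed
similarity verdict for each of the ten placentas from stillbirths of
unknown cause.  "Increased" in the original trophoblast column is
synonymous with High and is normalised here.
"""

from __future__ import annotations

from ..profiling import FeatureLevel, MorphometricProfile

_H = FeatureLevel.HIGH
_L = FeatureLevel.LOW
_U = FeatureLevel.UNCHANGED

# sample -> (SNAs, proliferation, vascularity, avascular, trophoblast,
#            leukocytes, printed verdict)
_TABLE = [
    ("Unknown 1", _L, _H, _U, _H, _L, _L, "Not similar"),
    ("Unknown 2", _H, _U, _L, _H, _U, _U, "Not similar"),
    ("Unknown 3", _H, _L, _L, _H, _H, _U, "Similar to FGR"),
    ("Unknown 4", _H, _U, _H, _U, _U, _U, "Not similar"),
    ("Unknown 5", _H, _L, _L, _H, _H, _U, "Similar to FGR"),
    ("Unknown 6", _H, _U, _L, _H, _U, _U, "Not similar"),
    ("Unknown 7", _U, _U, _L, _H, _U, _U, "Not similar"),
    ("Unknown 8", _U, _H, _L, _H, _H, _L, "Not similar"),
    ("Unknown 9", _H, _U, _L, _H, _H, _H, "Not similar"),
    ("Unknown 10", _U, _U, _L, _H, _H, _U, "Not similar"),
]


def table3_fixture() -> list[tuple[str, MorphometricProfile, str]]:
    """The ten transcribed unknown-cause profiles with their printed verdicts."""
    out = []
    for sample, snas, prolif, vasc, avasc, troph, leuk, verdict in _TABLE:
        profile = MorphometricProfile(
            sample_id=sample,
            levels={
                "snas": snas,
                "proliferation": prolif,
                "vascularity": vasc,
                "avascular": avasc,
                "trophoblast": troph,
                "leukocytes": leuk,
            },
        )
        out.append((sample, profile, verdict))
    return out
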