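"""Specificity profiles, relative affinity, and mJRL group classification.

A specificity profile maps each glycan of a panel to its dissociation and
association constants on one lectin column, with an explicit
below-detection flag (Ka reported as 0) for retardations under the floor
``v_min`` (default 0.5 uL).  Profiles are normalized per lectin to
relative affinity (percent of the strongest binder) and classified into
the mannose-binding jacalin-related lectin (mJRL) specificity scheme:

* group A — substantial binding across the high-mannose axis (the
  high-mannose class plus core-pentasaccharide glycans); otherwise B;
* subgroup 1 — binds complex-type glycans (agalacto / galactosylated /
  sialylated) broadly AND that binding is reduced by a bisecting GlcNAc;
* subgroup 2 — binds complex-type glycans without the bisecting penalty;
* unclassified — essentially no complex-type binding.

The numeric decision boundaries are explicit configuration
(:class:`ClassificationThresholds`), since the grouping scheme itself is
qualitative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ProfileEmptyError, ValidationError
from .fac_core import (
    ColumnCalibration,
    RetardationMeasurement,
    ka_from_kd,
    kd_from_retardation,
)
from .glycan_panel import COMPLEX_CLASSES, GlycanPanel

DEFAULT_V_MIN_UL = 0.5


@dataclass(frozen=True)
class ProfileEntry:
    kd_M: Optional[float]
    ka_per_M: float
    below_detection: bool


@dataclass(frozen=True)
class SpecificityProfile:
    """Per-glycan binding constants of one lectin over a panel."""

    lectin_name: str
    entries: dict[str, ProfileEntry]
    calibration: ColumnCalibration
    v_min_uL: float = DEFAULT_V_MIN_UL

    def detectable_ids(self) -> set[str]:
        return {g for g, e in self.entries.items() if not e.below_detection}

    @property
    def detection_limit_ka(self) -> float:
        """Ka at the detection floor: 1 / (Bt / (v_min * 1e3))."""
        return self.v_min_uL * 1e3 / self.calibration.bt_nmol


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision boundaries for mJRL grouping; all must lie in (0, 1)."""

    theta_A: float = 0.2  # min detectable fraction on the high-mannose axis
    theta_C: float = 0.5  # complex-type fraction required for subgroup 1
    theta_min: float = 0.1  # complex-type fraction below which unclassified
    rho: float = 0.5  # max bisecting/non-bisecting mean affinity ratio

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not 0 < val < 1:
                raise ValidationError(f"threshold {name}={val} outside (0, 1)")


@dataclass(frozen=True)
class GroupAssignment:
    """mJRL specificity group with the numeric evidence behind it."""

    lectin_name: str
    group: str  # "A" or "B"
    subgroup: str  # "1", "2", or "unclassified"
    evidence: dict[str, float] = field(default_factory=dict)


def build_profile(
    measurements: Sequence[RetardationMeasurement],
    calibration: ColumnCalibration,
    panel: GlycanPanel,
    v_min_uL: float = DEFAULT_V_MIN_UL,
) -> SpecificityProfile:
    """Assemble a profile: below-detection rule, then Kd and Ka per glycan.

    Every glycan of the panel appears in the result; panel glycans without
    a measurement are flagged below detection with a warning.  Measurements
    for glycans absent from the panel are an error.
    """
    panel_ids = set(panel.ids)
    unknown = sorted({m.glycan_id for m in measurements} - panel_ids)
    if unknown:
        raise ValidationError(f"measurements for glycans not in panel: {unknown}")
    entries: dict[str, ProfileEntry] = {}
    for m in measurements:
        if m.below_detection or m.v_minus_v0_uL <= v_min_uL:
            entries[m.glycan_id] = ProfileEntry(None, 0.0, True)
            continue
        kd = kd_from_retardation(calibration.bt_nmol, m.v_minus_v0_uL, m.a0_M)
        if kd is None:
            warnings.warn(
                f"glycan {m.glycan_id}: retardation inconsistent with model; "
                "flagged below detection",
                stacklevel=2,
            )
            entries[m.glycan_id] = ProfileEntry(None, 0.0, True)
        else:
            entries[m.glycan_id] = ProfileEntry(kd, ka_from_kd(kd), False)
    missing = [g for g in panel.ids if g not in entries]
    if missing:
        warnings.warn(
            f"{len(missing)} panel glycan(s) without measurements flagged "
            "below detection",
            stacklevel=2,
        )
        for g in missing:
            entries[g] = ProfileEntry(None, 0.0, True)
    ordered = {g: entries[g] for g in panel.ids}
    return SpecificityProfile(
        lectin_name=calibration.lectin_name,
        entries=ordered,
        calibration=calibration,
        v_min_uL=v_min_uL,
    )


def relative_affinity(profile: SpecificityProfile) -> dict[str, float]:
    """Percent of the profile's maximum Ka; below detection maps to 0."""
    kas = {g: e.ka_per_M for g, e in profile.entries.items()}
    top = max(kas.values())
    if top <= 0:
        raise ProfileEmptyError(
            f"profile {profile.lectin_name!r} empty: all entries below detection"
        )
    return {g: 100.0 * ka / top for g, ka in kas.items()}


def _detectable_fraction(profile: SpecificityProfile, ids: Sequence[str]) -> float:
    if not ids:
        return 0.0
    det = profile.detectable_ids()
    return sum(1 for g in ids if g in det) / len(ids)


def classify_mjrl(
    profile: SpecificityProfile,
    panel: GlycanPanel,
    thresholds: ClassificationThresholds | None = None,
) -> GroupAssignment:
    """Assign an mJRL specificity group/subgroup from a profile.

    Depends only on detectable fractions and relative (rescaling-invariant)
    affinities.  The high-mannose axis includes core-pentasaccharide
    glycans: lectins that bind only the trimmed Man3GlcNAc2 core among the
    mannose glycans are still mannose-axis binders.
    """
    th = thresholds or ClassificationThresholds()
    mannose_axis = sorted(
        set(panel.ids_in_classes(["high_mannose"]))
        | set(panel.ids_with_motif("core_pentasaccharide"))
    )
    complex_ids = list(panel.ids_in_classes(COMPLEX_CLASSES))
    bisecting = [g for g in complex_ids if panel.get(g).has_motif("bisecting_glcnac")]
    non_bisecting = [g for g in complex_ids if g not in set(bisecting)]

    frac_mannose = _detectable_fraction(profile, mannose_axis)
    frac_complex = _detectable_fraction(profile, complex_ids)
    rel = relative_affinity(profile)
    mean_bis = float(np.mean([rel[g] for g in bisecting])) if bisecting else 0.0
    mean_nonbis = (
        float(np.mean([rel[g] for g in non_bisecting])) if non_bisecting else 0.0
    )

    group = "A" if frac_mannose >= th.theta_A else "B"
    evidence = {
        "mannose_axis_fraction": frac_mannose,
        "complex_fraction": frac_complex,
        "bisecting_mean_relative_affinity": mean_bis,
        "non_bisecting_mean_relative_affinity": mean_nonbis,
    }
    if frac_complex < th.theta_min:
        subgroup = "unclassified"
        evidence["failing_criterion_complex_fraction_min"] = th.theta_min
    else:
        bisecting_reduced = mean_bis <= th.rho * mean_nonbis and mean_nonbis > 0
        evidence["bisecting_reduced"] = float(bisecting_reduced)
        subgroup = "1" if frac_complex >= th.theta_C and bisecting_reduced else "2"
    return GroupAssignment(
        lectin_name=profile.lectin_name,
        group=group,
        subgroup=subgroup,
        evidence=evidence,
    )


def compare_profiles(
    p1: SpecificityProfile,
    p2: SpecificityProfile,
    panel: GlycanPanel,
    gap: float = 1.0,
) -> dict:
    """Concordance and discordant glycans between two profiles.

    Concordance is the Pearson correlation of log10(Ka + floor) over the
    glycans detectable in *both* profiles (floor = each profile's
    detection-limit Ka), so a uniform affinity rescaling — e.g. the
    global ~100-fold offset between a strong and weak paralog — scores 1.
    Discordant glycans are those detectable in exactly one profile, or
    whose log10 Ka ratio deviates from the global median offset by more
    than ``gap`` decades.
    """
    ids = list(panel.ids)
    for p in (p1, p2):
        if set(p.entries) != set(ids):
            raise ValidationError(
                f"profile {p.lectin_name!r} does not cover the panel"
            )
    det1, det2 = p1.detectable_ids(), p2.detectable_ids()
    both = [g for g in ids if g in det1 and g in det2]
    one_sided = [g for g in ids if (g in det1) != (g in det2)]

    if not both:
        return {
            "concordance": None,
            "discordant": sorted(one_sided),
            "median_log10_offset": None,
            "note": "disjoint detectable sets: concordance undefined",
        }
    f1, f2 = p1.detection_limit_ka, p2.detection_limit_ka
    x = np.log10([p1.entries[g].ka_per_M + f1 for g in both])
    y = np.log10([p2.entries[g].ka_per_M + f2 for g in both])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        concordance = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else None
    else:
        concordance = float(np.corrcoef(x, y)[0, 1])
    delta = x - y
    median_offset = float(np.median(delta))
    outliers = [g for g, d in zip(both, delta) if abs(d - median_offset) > gap]
    return {
        "concordance": concordance,
        "discordant": sorted(set(one_sided) | set(outliers)),
        "median_log10_offset": median_offset,
    }


# --- JSON persistence -------------------------------------------------------

def profile_to_dict(profile: SpecificityProfile) -> dict:
    cal = profile.calibration
    return {
        "lectin": profile.lectin_name,
        "v_min_uL": profile.v_min_uL,
        "calibration": {
            "lectin_name": cal.lectin_name,
            "Bt_nmol": cal.bt_nmol,
            "Kd_ref_M": cal.kd_ref_M,
            "bed_volume_uL": cal.bed_volume_uL,
            "r2": cal.r2,
        },
        "entries": [
            {
                "glycan_id": g,
                "Kd_M": e.kd_M,
                "Ka_per_M": e.ka_per_M,
                "below_detection": e.below_detection,
            }
            for g, e in profile.entries.items()
        ],
    }


def profile_from_dict(data: dict) -> SpecificityProfile:
    cal = data["calibration"]
    calibration = ColumnCalibration(
        lectin_name=cal["lectin_name"],
        bt_nmol=cal["Bt_nmol"],
        kd_ref_M=cal["Kd_ref_M"],
        bed_volume_uL=cal.get("bed_volume_uL"),
        r2=cal.get("r2"),
    )
    entries = {
        e["glycan_id"]: ProfileEntry(e["Kd_M"], e["Ka_per_M"], e["below_detection"])
        for e in data["entries"]
    }
    return SpecificityProfile(
        lectin_name=data["lectin"],
        entries=entries,
        calibration=calibration,
        v_min_uL=data.get("v_min_uL", DEFAULT_V_MIN_UL),
    )


def save_profile(profile: SpecificityProfile, path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_dict(profile), fh, indent=1)


def load_profile(path) -> SpecificityProfile:
    with open(path) as fh:
        return profile_from_dict(json.load(fh))
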