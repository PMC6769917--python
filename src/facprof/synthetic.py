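"""Synthetic data generation for every pipeline stage.

The instrument and the full 130-glycan appendix panel are unavailable, so
this module generates a stated stand-in world:

* a 130-glycan archetype panel — 61 N-linked glycans across the five
  N-glycan classes, 39 glycolipid-type glycans and 30 others — carrying
  sentinel glycans with the motifs the downstream biology turns on:
  "003"/"015" (trimmed Man3GlcNAc2 core pentasaccharide), "017" (plant
  fucose/xylose core), "913" (Man-alpha1-3-Man only) and "914"/"915"
  (Man-alpha1-6-Man only);
* three lectin archetypes: ``PPL2A_like`` binds agalacto/galactosylated/
  sialylated complex glycans plus the core pentasaccharide at Kd around
  2e-7 M, skipping bisecting-GlcNAc, tetraantennary and plant-core
  glycans; ``PPL3_like`` has the same support plus the plant-core glycan
  "017" at ~100x weaker affinity (Kd ~2e-5 M); ``PPL4_like`` binds
  high-mannose/hybrid glycans, Man-alpha1-6-Man-containing glycolipids
  and chitin-type glycans (Kd ~2e-5 M) and no complex-type glycans;
* sigmoid (normal-CDF) breakthrough fronts with multiplicative
  fluorescence noise, concentration-dependence calibration series, and
  deterministic 2-fold HAI dilution plates.

Per-glycan log10-Kd deviations (sd 0.3, clipped at +-3 sd) are drawn from
an RNG keyed by (seed, glycan id), so archetypes sharing support differ by
their Kd centers alone — the "similar profile, ~100-fold offset" world.
All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

from .errors import ValidationError
from .fac_core import CalibrationPoint, ColumnCalibration, retardation_forward
from .front_detection import ElutionCurve
from .glycan_panel import COMPLEX_CLASSES, GlycanPanel, GlycanRecord
from .hai import DilutionSeries

ARCHETYPE_NAMES = ("PPL2A_like", "PPL3_like", "PPL4_like", "nonbinder")

#: Column calibrations as printed for the three lectin columns: effective
#: ligand content Bt (nmol) and the calibration ligand's Kd (M), on the
#: standard 2 x 10 mm (31.4 uL) miniature column.
REFERENCE_CALIBRATIONS = {
    "PPL2A": ColumnCalibration("PPL2A", bt_nmol=0.02, kd_ref_M=2.0e-7,
                               bed_volume_uL=31.4),
    "PPL3s": ColumnCalibration("PPL3s", bt_nmol=0.63, kd_ref_M=3.01e-5,
                               bed_volume_uL=31.4),
    "PPL4": ColumnCalibration("PPL4", bt_nmol=0.98, kd_ref_M=2.0e-5,
                              bed_volume_uL=31.4),
}

ARCHETYPE_COLUMN = {
    "PPL2A_like": "PPL2A",
    "PPL3_like": "PPL3s",
    "PPL4_like": "PPL4",
    "nonbinder": "PPL3s",
}

_LOG10_SD = 0.3
_KD_CENTER_STRONG = 2.0e-7
_KD_CENTER_WEAK = 2.0e-5


@dataclass(frozen=True)
class LectinArchetype:
    """Qualitative binding rules of one lectin archetype."""

    name: str
    kd_center_M: float
    log10_sd: float = _LOG10_SD
    bind_classes: frozenset[str] = frozenset()
    bind_motifs: frozenset[str] = frozenset()
    skip_motifs: frozenset[str] = frozenset()
    exceptions: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd_center_M is not None and not self.kd_center_M > 0:
            raise ValidationError("Kd center must be positive")
        if self.log10_sd < 0:
            raise ValidationError("log10 sd must be non-negative")

    def binds(self, rec: GlycanRecord) -> bool:
        if rec.id in self.exceptions:
            return self.exceptions[rec.id] is not None
        if any(m in rec.motifs for m in self.skip_motifs):
            return False
        if rec.glycan_class in self.bind_classes:
            return True
        return any(m in rec.motifs for m in self.bind_motifs)


def get_archetype(name: str) -> LectinArchetype:
    if name == "PPL2A_like":
        return LectinArchetype(
            name=name,
            kd_center_M=_KD_CENTER_STRONG,
            bind_classes=frozenset(COMPLEX_CLASSES),
            bind_motifs=frozenset({"core_pentasaccharide"}),
            skip_motifs=frozenset({"bisecting_glcnac", "four_branch"}),
            exceptions={"017": None},
        )
    if name == "PPL3_like":
        return LectinArchetype(
            name=name,
            kd_center_M=_KD_CENTER_WEAK,
            bind_classes=frozenset(COMPLEX_CLASSES),
            bind_motifs=frozenset({"core_pentasaccharide"}),
            skip_motifs=frozenset({"bisecting_glcnac", "four_branch"}),
            exceptions={"017": _KD_CENTER_WEAK},
        )
    if name == "PPL4_like":
        return LectinArchetype(
            name=name,
            kd_center_M=_KD_CENTER_WEAK,
            bind_classes=frozenset({"high_mannose", "hybrid"}),
            bind_motifs=frozenset({"man_a1_6_man", "chitin_type"}),
            skip_motifs=frozenset(),
            # complex classes are excluded by construction of bind_classes;
            # alpha1-3-only mannose arms are not recognized
            exceptions={"913": None},
        )
    if name == "nonbinder":
        return LectinArchetype(
            name=name, kd_center_M=_KD_CENTER_WEAK, bind_classes=frozenset()
        )
    raise ValidationError(f"unknown archetype {name!r}; expected {ARCHETYPE_NAMES}")


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument surrogate settings.

    ``a0_M`` defaults to the 2.5 nM PA-glycan infusion concentration;
    ``v0_true_uL`` to the 31.4 uL bed volume of the miniature column;
    the front is a normal CDF of width ``front_sigma_uL`` with additive
    Gaussian noise of sd ``noise_cv`` x plateau.
    """

    seed: int = 0
    a0_M: float = 2.5e-9
    front_sigma_uL: float = 1.5
    noise_cv: float = 0.02
    v_grid: tuple[float, float, float] = (0.0, 1200.0, 0.25)
    v0_true_uL: float = 31.4

    def __post_init__(self) -> None:
        start, stop, step = self.v_grid
        if step <= 0 or stop <= start:
            raise ValidationError("v_grid must have positive step and extent")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if not self.a0_M > 0:
            raise ValidationError("A0 must be positive")

    @property
    def volumes(self) -> np.ndarray:
        start, stop, step = self.v_grid
        return np.arange(start, stop + 0.5 * step, step)


def _glycan_salt(glycan_id: str) -> int:
    return zlib.crc32(glycan_id.encode("utf-8"))


def _rng(seed: int, *salts: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *salts])


# stable per-operation salts so fixture streams are independent
_SALT_CURVE = 101
_SALT_CALIB = 202
_SALT_HAI = 303
_SALT_AFFINITY = 404


def make_archetype_panel(seed: int = 0) -> GlycanPanel:
    """The 130-glycan stand-in panel (deterministic; seed kept for API).

    61 N-linked (9 high-mannose, 6 hybrid, 18 agalacto, 16 galactosylated,
    12 sialylated), 39 glycolipid-type, 30 others.  Sentinels: "003"/"015"
    core pentasaccharide; "017" plant fucose/xylose core; "913" alpha1-3
    arm only; "914"/"915" alpha1-6 arm only; chitin oligomers "101"-"104".
    """
    records: list[GlycanRecord] = []

    def add(gid, name, cls, *motifs):
        records.append(GlycanRecord(gid, name, cls, frozenset(motifs)))

    # high-mannose (9): Man5-Man9 series plus trimmed cores
    add("001", "Man9GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("002", "Man8GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("003", "Man3GlcNAc2 core", "high_mannose", "core_pentasaccharide",
        "man_a1_6_man", "man_a1_3_man")
    add("004", "Man7GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("005", "Man6GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("006", "Man5GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("007", "Man5GlcNAc2 isomer", "high_mannose", "man_a1_6_man")
    add("008", "Man4GlcNAc2", "high_mannose", "man_a1_6_man", "man_a1_3_man")
    add("015", "Man3GlcNAc2 core (PA)", "high_mannose", "core_pentasaccharide",
        "man_a1_6_man", "man_a1_3_man")
    # hybrid (6)
    for i, gid in enumerate(["009", "010", "011", "012", "013", "014"]):
        motifs = ["man_a1_6_man"]
        if i == 2:
            motifs.append("bisecting_glcnac")
        add(gid, f"Hybrid-{i + 1}", "hybrid", *motifs)
    # plant-core sentinel
    add("017", "Man3Fuc1Xyl1GlcNAc2", "other", "plant_fuc_xyl_core")
    # agalacto complex (18): ids 016, 018-034
    agalacto_ids = ["016"] + [f"{i:03d}" for i in range(18, 35)]
    for i, gid in enumerate(agalacto_ids):
        motifs = []
        if i in (2, 7, 12):
            motifs.append("bisecting_glcnac")
        if i in (4, 14):
            motifs.append("four_branch")
        add(gid, f"Agalacto-biantennary-{i + 1}", "agalacto", *motifs)
    # galactosylated complex (16): 035-050
    for i, gid in enumerate(f"{i:03d}" for i in range(35, 51)):
        motifs = []
        if i in (3, 9):
            motifs.append("bisecting_glcnac")
        if i in (6, 13):
            motifs.append("four_branch")
        add(gid, f"Galactosylated-{i + 1}", "galactosylated", *motifs)
    # sialylated complex (12): 051-062
    for i, gid in enumerate(f"{i:03d}" for i in range(51, 63)):
        motifs = []
        if i == 5:
            motifs.append("bisecting_glcnac")
        if i == 8:
            motifs.append("four_branch")
        add(gid, f"Sialylated-{i + 1}", "sialylated", *motifs)
    # glycolipid-type (39): 901-939 with mannose-arm sentinels
    for i, gid in enumerate(f"{i:03d}" for i in range(901, 940)):
        if gid == "913":
            add(gid, "Glycolipid Man-a1-3 arm", "glycolipid", "man_a1_3_man")
        elif gid in ("914", "915"):
            add(gid, "Glycolipid Man-a1-6 arm", "glycolipid", "man_a1_6_man")
        else:
            add(gid, f"Glycolipid-{i + 1}", "glycolipid")
    # others (29 more): chitin oligomers and free saccharides, 101-129
    for i, gid in enumerate(f"{i:03d}" for i in range(101, 130)):
        if i < 4:
            add(gid, f"Chitin oligomer GlcNAc{i + 2}", "other", "chitin_type")
        else:
            add(gid, f"Other-saccharide-{i + 1}", "other")

    return GlycanPanel(
        records=tuple(records),
        provenance=f"synthetic archetype panel (seed={seed})",
    )


def true_affinities(
    archetype: LectinArchetype, panel: GlycanPanel, seed: int
) -> dict[str, Optional[float]]:
    """Ground-truth Kd (M) per glycan, None where the archetype is blind.

    The per-glycan log10 deviation stream is keyed by (seed, glycan id)
    and shared across archetypes, so paralogs with common support differ
    only by their Kd centers.
    """
    out: dict[str, Optional[float]] = {}
    for rec in panel:
        if not archetype.binds(rec):
            out[rec.id] = None
            continue
        override = archetype.exceptions.get(rec.id)
        center = override if override is not None else archetype.kd_center_M
        rng = _rng(seed, _SALT_AFFINITY, _glycan_salt(rec.id))
        dev = float(
            np.clip(
                rng.normal(0.0, archetype.log10_sd),
                -3 * archetype.log10_sd,
                3 * archetype.log10_sd,
            )
        )
        out[rec.id] = center * 10.0**dev
    return out


def simulate_elution_curve(
    v_front_true_uL: float,
    cfg: SimulationConfig,
    seed: int,
    plateau: float = 1.0,
    analyte_id: str | None = None,
) -> ElutionCurve:
    """Sigmoid breakthrough front plus Gaussian fluorescence noise.

    signal = plateau * Phi((v - v_front)/sigma) + N(0, noise_cv*plateau).
    Deterministic given (seed, cfg).
    """
    v = cfg.volumes
    if not (v[0] < v_front_true_uL < v[-1]):
        raise ValidationError(
            f"true front {v_front_true_uL:.1f} uL outside the volume grid"
        )
    if cfg.v_grid[2] > cfg.front_sigma_uL:
        warnings.warn("grid step exceeds front width; front will be aliased",
                      stacklevel=2)
    signal = plateau * ndtr((v - v_front_true_uL) / cfg.front_sigma_uL)
    if cfg.noise_cv > 0:
        rng = _rng(seed, _SALT_CURVE)
        signal = signal + rng.normal(0.0, cfg.noise_cv * plateau, size=v.size)
    meta = {"excitation_nm": 310, "emission_nm": 380}
    if analyte_id is not None:
        meta["analyte_id"] = analyte_id
    return ElutionCurve(volumes=v, signal=signal, meta=meta)


def simulate_calibration_series(
    bt_nmol: float,
    kd_M: float,
    a0_list_M: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Concentration-dependence series with multiplicative noise.

    Default design: [A]0 at {0.1, 0.3, 1, 3, 10} x Kd (the instrument's
    actual concentration ladder is not published; this spans the
    saturation curve symmetrically around Kd).
    """
    if a0_list_M is None:
        a0_list_M = [f * kd_M for f in (0.1, 0.3, 1.0, 3.0, 10.0)]
    if not a0_list_M:
        raise ValidationError("A0 list must be non-empty")
    rng = _rng(seed, _SALT_CALIB)
    points = []
    for a0 in a0_list_M:
        if a0 <= 0:
            raise ValidationError("A0 values must be positive")
        v = retardation_forward(bt_nmol, kd_M, a0)
        if noise_cv > 0:
            v *= 1.0 + rng.normal(0.0, noise_cv)
        points.append(CalibrationPoint(a0_M=a0, v_minus_v0_uL=v))
    return points


def simulate_hai_plate(
    true_mic: float,
    start_conc: float,
    factor: float = 2.0,
    n_wells: int = 8,
    unit: str = "mM",
    flip_rate: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Deterministic plate: well k inhibits iff start/factor^k >= true MIC.

    ``flip_rate`` flips wells at random for robustness tests only.
    """
    if start_conc <= 0 or true_mic <= 0:
        raise ValidationError("concentrations must be positive")
    outcomes = [start_conc / factor**k >= true_mic for k in range(n_wells)]
    if flip_rate > 0:
        rng = _rng(seed, _SALT_HAI)
        flips = rng.random(n_wells) < flip_rate
        outcomes = [o ^ bool(f) for o, f in zip(outcomes, flips)]
    return DilutionSeries(start_conc=start_conc, unit=unit,
                          outcomes=tuple(outcomes), factor=factor)
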