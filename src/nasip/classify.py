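"""Three-criterion classification of 13C-labelled OTUs.

An OTU in a labelled-substrate gradient is called 13C-labelled when

1. its maximum relative abundance in the *heavy* fractions exceeds its
   maximum relative abundance anywhere in the control gradient by more
   than ``delta_points`` percentage points (inter-gradient comparison);
2. its maximum heavy-fraction abundance exceeds its maximum
   light-fraction abundance by more than ``delta_points`` points
   (intra-gradient evaluation); and
3. "heavy" is defined by a density threshold calibrated on fully
   labelled vs unlabelled nucleic-acid standards (E. coli), with fixed
   fallbacks of 1.797 g/ml (RNA, CsTFA) and 1.702 g/ml (DNA, CsCl).

Both threshold criteria must pass.  OTUs that are effectively absent
from the control gradient (high specificity, no background) are instead
called by a presence rule: detection in any heavy fraction of the
labelled gradient is itself evidence of label incorporation.

Labelled calls are graded by how deep into the gradient the OTU peaks:
at or beyond ``strong_density`` the nucleic acid is strongly (near fully)
labelled, otherwise partially labelled — increasing density reports an
increasing degree of 13C substitution.

A GC-content check guards the density logic for DNA: unlabelled
high-GC DNA bands heavy on its own, so a heavy call for a taxon whose
unlabelled buoyant density already reaches the threshold is flagged as
potentially GC-driven.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np
import pandas as pd

from nasip.errors import DomainError, NasipError
from nasip.fractions import FractionTable
from nasip.gradient import Medium, bd_unlabelled

_TIE_EPS = 1e-9  # guards the strict ">" at the percentage-point boundary

#: Fallback heavy-window thresholds (g/ml) when no standards are available.
FIXED_THRESHOLD = {Medium.CSTFA_RNA: 1.797, Medium.CSCL_DNA: 1.702}
#: Density at which a labelled call is graded "strong" rather than "partial".
FIXED_STRONG = {Medium.CSTFA_RNA: 1.816, Medium.CSCL_DNA: 1.714}


class Status(str, enum.Enum):
    UNLABELLED = "unlabelled"
    PARTIALLY_LABELLED = "partially_labelled"
    STRONGLY_LABELLED = "strongly_labelled"
    PRESENT_IN_HEAVY = "present_in_heavy"


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    medium: Medium
    threshold_density: float
    strong_density: float
    source: str  # "standards" or "fixed"

    def __post_init__(self) -> None:
        if self.strong_density < self.threshold_density:
            raise DomainError("strong_density must be >= threshold_density")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Tunable classification thresholds.

    ``delta_points`` is the minimum increase, in percentage points of
    total-sum-scaled relative abundance, that criteria 1 and 2 must
    exceed (strictly).  ``background_floor`` is the relative abundance
    below which an OTU counts as not detectable in controls and is
    routed to the presence rule.
    """

    delta_points: float = 5.0
    background_floor: float = 0.001

    def __post_init__(self) -> None:
        if not self.delta_points > 0:
            raise DomainError("delta_points must be positive")


@dataclasses.dataclass(frozen=True)
class LabelCall:
    otu_id: str
    status: Status
    criterion1: bool
    criterion2: bool
    background: str  # "high" or "low"
    peak_density: float
    evidence: dict
    gc_warning: bool = False


@dataclasses.dataclass(frozen=True)
class WindowMap:
    """Fraction ids split at the calibrated threshold, with rank labels
    (heavy / middle / light / ultra-light) for reporting."""

    heavy: tuple[str, ...]
    light: tuple[str, ...]
    rank_labels: dict


def fixed_calibration(medium: Medium | str) -> CalibrationResult:
    """Literature fallback thresholds, no standards required."""
    medium = Medium.parse(medium)
    return CalibrationResult(
        medium, FIXED_THRESHOLD[medium], FIXED_STRONG[medium], source="fixed"
    )


def _standard_profile(table: FractionTable) -> np.ndarray:
    if len(table.otu_ids) != 1:
        raise NasipError(
            f"standard gradient must contain a single species, got {table.otu_ids}"
        )
    if table.scaled:
        raise NasipError("standards must carry the raw mass profile, not scaled data")
    return np.nan_to_num(table.values.iloc[0].to_numpy(), nan=0.0)


def calibrate(
    standards: tuple[FractionTable, FractionTable],
    *,
    ratio: float = 2.0,
    floor: float = 0.01,
    strong_offset: float | None = None,
) -> CalibrationResult:
    """Derive the heavy-window threshold from standard gradients.

    ``standards`` is (unlabelled, labelled), each a single-species mass
    profile across the same fraction grid.  The threshold is the lowest
    density at which the labelled standard's per-fraction mass both
    exceeds the unlabelled standard's by ``ratio`` and holds at least
    ``floor`` of the labelled standard's total — i.e. the light edge of
    the band that only labelled material reaches.  If no fraction
    qualifies (e.g. the standards coincide), falls back to the fixed
    thresholds with a warning.
    """
    unlab, lab = standards
    medium = Medium.parse(lab.medium or unlab.medium)
    if unlab.fraction_ids != lab.fraction_ids or not np.allclose(
        unlab.densities, lab.densities
    ):
        raise NasipError("standard gradients must share one fraction grid")
    u = _standard_profile(unlab)
    l = _standard_profile(lab)
    l_total = l.sum()
    if l_total <= 0:
        raise NasipError("labelled standard carries no mass")
    qualifying = (l > ratio * u) & (l >= floor * l_total)
    if strong_offset is None:
        strong_offset = FIXED_STRONG[medium] - FIXED_THRESHOLD[medium]
    if not qualifying.any():
        warnings.warn(
            "standards do not separate; falling back to fixed thresholds",
            stacklevel=2,
        )
        return fixed_calibration(medium)
    dens = lab.densities.to_numpy()
    threshold = float(dens[qualifying].min())
    return CalibrationResult(
        medium, threshold, threshold + strong_offset, source="standards"
    )


def partition_windows(table: FractionTable, cal: CalibrationResult) -> WindowMap:
    """Assign each fraction to the heavy (density >= threshold) or light
    window, and rank non-missing fractions heavy / middle / light /
    ultra-light for reporting."""
    heavy, light = [], []
    for fid in table.fraction_ids:
        (heavy if table.densities[fid] >= cal.threshold_density else light).append(fid)
    present = table.present_fractions()  # already ordered heaviest first
    rank_labels: dict = {}
    names = ("heavy", "middle", "light", "ultra-light")
    for name, chunk in zip(names, np.array_split(np.array(present, dtype=object), 4)):
        for fid in chunk:
            rank_labels[str(fid)] = name
    return WindowMap(tuple(heavy), tuple(light), rank_labels)


def _window_max(table: FractionTable, otu: str, fids) -> float:
    """Max relative abundance of the OTU over the given non-missing
    fractions; 0.0 when no usable fraction exists."""
    if otu not in table.values.index:
        raise NasipError(f"OTU {otu!r} absent from table")
    vals = [
        table.abundance(otu, f) for f in fids if f in table.fraction_ids
        and not table.missing[f]
    ]
    vals = [v for v in vals if not np.isnan(v)]
    return max(vals) if vals else 0.0


def criterion_inter(
    otu: str,
    labelled: FractionTable,
    control: FractionTable,
    windows: WindowMap,
    thr: Thresholds = Thresholds(),
) -> tuple[bool, dict]:
    """Inter-gradient comparison: heavy-window max in the labelled
    gradient must exceed the OTU's maximum over ALL control fractions by
    more than ``delta_points`` percentage points."""
    heavy_max = _window_max(labelled, otu, windows.heavy)
    control_max = _window_max(control, otu, control.fraction_ids)
    passed = (heavy_max - control_max) * 100.0 > thr.delta_points + _TIE_EPS
    return passed, {
        "heavy_max_pct": heavy_max * 100.0,
        "control_max_pct": control_max * 100.0,
    }


def criterion_intra(
    otu: str,
    labelled: FractionTable,
    windows: WindowMap,
    thr: Thresholds = Thresholds(),
) -> tuple[bool, dict]:
    """Intra-gradient evaluation: heavy-window max minus light-window max
    must exceed ``delta_points`` percentage points."""
    heavy_max = _window_max(labelled, otu, windows.heavy)
    light_max = _window_max(labelled, otu, windows.light)
    passed = (heavy_max - light_max) * 100.0 > thr.delta_points + _TIE_EPS
    return passed, {
        "heavy_max_pct": heavy_max * 100.0,
        "light_max_pct": light_max * 100.0,
    }


def presence_rule(
    otu: str,
    labelled: FractionTable,
    control: FractionTable,
    windows: WindowMap,
    thr: Thresholds = Thresholds(),
) -> bool:
    """Call low-background OTUs by detection in the heavy window.

    Applies only when the OTU's maximum control abundance is below
    ``background_floor``; then any heavy-window detection above that
    floor in the labelled gradient evidences label incorporation."""
    control_max = _window_max(control, otu, control.fraction_ids)
    if control_max >= thr.background_floor:
        return False
    return _window_max(labelled, otu, windows.heavy) > thr.background_floor


def _peak_density(table: FractionTable, otu: str) -> float:
    best, best_v = float("nan"), -np.inf
    for fid in table.fraction_ids:
        if table.missing[fid]:
            continue
        v = table.abundance(otu, fid)
        if not np.isnan(v) and v > best_v:
            best, best_v = float(table.densities[fid]), v
    return best


def gc_confound_check(
    gc: float, medium: Medium | str, cal: CalibrationResult, **bd_kwargs
) -> bool:
    """True (no confound) iff unlabelled nucleic acid of this GC bands
    below the heavy threshold, so heavy-window presence cannot be a pure
    base-composition effect."""
    return bd_unlabelled(gc, medium, **bd_kwargs) < cal.threshold_density


def classify(
    otu: str,
    labelled: FractionTable,
    control: FractionTable,
    cal: CalibrationResult,
    thr: Thresholds = Thresholds(),
    gc: float | None = None,
) -> LabelCall:
    """Full per-OTU call combining the criteria.

    High-background OTUs (detectable in controls) must pass criteria 1
    AND 2; low-background OTUs are routed to the presence rule and called
    ``present_in_heavy``.  Labelled high-background calls are graded
    strongly/partially by whether the OTU's peak fraction density reaches
    ``cal.strong_density``.  Passing ``gc`` enables the GC-confound
    check; a confounded heavy call is downgraded to a warning flag.
    """
    if not labelled.scaled or not control.scaled:
        raise NasipError("classify expects total-sum-scaled tables")
    windows = partition_windows(labelled, cal)
    c1, ev1 = criterion_inter(otu, labelled, control, windows, thr)
    c2, ev2 = criterion_intra(otu, labelled, windows, thr)
    control_max = ev1["control_max_pct"] / 100.0
    background = "high" if control_max >= thr.background_floor else "low"
    evidence = {**ev1, "light_max_pct": ev2["light_max_pct"]}
    peak = _peak_density(labelled, otu)

    if background == "low":
        hit = presence_rule(otu, labelled, control, windows, thr)
        status = Status.PRESENT_IN_HEAVY if hit else Status.UNLABELLED
    elif c1 and c2:
        status = (
            Status.STRONGLY_LABELLED
            if peak >= cal.strong_density
            else Status.PARTIALLY_LABELLED
        )
    else:
        status = Status.UNLABELLED

    gc_warning = False
    if gc is not None and status is not Status.UNLABELLED:
        if not gc_confound_check(gc, cal.medium, cal):
            gc_warning = True
            warnings.warn(
                f"OTU {otu!r}: unlabelled nucleic acid at GC={gc:.2f} already "
                f"bands above {cal.threshold_density:.3f} g/ml; heavy-window "
                "presence may be GC-driven",
                stacklevel=2,
            )
    return LabelCall(otu, status, c1, c2, background, peak, evidence, gc_warning)


def classify_table(
    labelled: FractionTable,
    control: FractionTable,
    cal: CalibrationResult,
    thr: Thresholds = Thresholds(),
    gc_map: dict | None = None,
) -> pd.DataFrame:
    """Classify every OTU shared by the labelled and control tables.

    Returns one row per OTU: status, criterion flags, background class,
    peak density, and the evidence percentages."""
    rows = []
    for otu in labelled.otu_ids:
        if otu not in control.values.index:
            raise NasipError(f"OTU {otu!r} missing from control table")
        gc = gc_map.get(otu) if gc_map else None
        call = classify(otu, labelled, control, cal, thr, gc=gc)
        rows.append(
            {
                "otu_id": call.otu_id,
                "status": call.status.value,
                "criterion1": call.criterion1,
                "criterion2": call.criterion2,
                "background": call.background,
                "peak_density": call.peak_density,
                "gc_warning": call.gc_warning,
                **call.evidence,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")
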