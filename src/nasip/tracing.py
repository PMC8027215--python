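"""Carbon atom tracing into nucleic-acid ribose, and δ13C utilities.

The model follows carbon through the reactions that matter for
nucleic-acid labelling in SIP incubations, at the level of per-carbon
label probabilities (the expected 13C fraction at each carbon position),
which is all the gradient physics responds to:

* Heterotrophic growth on unlabelled organic substrates still fixes
  CO2: acetyl-CoA (2C, unlabelled) is carboxylated to pyruvate (3C)
  with one DIC-derived carbon.  With fully 13C-labelled DIC this lifts
  pyruvate to a 1/3 ≈ 33% atom fraction.
* Two pyruvate-derived trioses condense to a hexulose
  (arabino-3-hexulose-6-phosphate); cleaving the formaldehyde-derived,
  organic (unlabelled) carbon leaves five ribose carbons, raising the
  atom fraction to 2/5 = 40% — partial labelling, i.e. a mixotrophic
  signature.
* Lactate feeds pyruvate directly (oxidation moves no carbon), so a
  uniformly 13C-labelled lactate yields near-fully labelled ribose.
* A fully autotrophic route (Wood-Ljungdahl) makes every ribose carbon
  DIC-derived.

Isotope utilities convert between δ13C (‰ vs VPDB) and atom fraction
and mix new biomass into a total-organic-carbon pool, the mass balance
behind using δ13C-TOC time courses as an assimilation proxy.
"""

from __future__ import annotations

import dataclasses
import enum

from nasip.classify import CalibrationResult, Status
from nasip.errors import DomainError
from nasip.gradient import Medium, bd_unlabelled, density_shift

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0111802

#: Unlabelled buoyant density (g/ml) used when predicting band positions
#: from a traced atom fraction: typical rRNA (GC ~50-60 mol%) in CsTFA,
#: and low-GC archaeal DNA (GC 0.30) via the Schildkraut map in CsCl.
TYPICAL_UNLABELLED_BD = {
    Medium.CSTFA_RNA: 1.784,
    Medium.CSCL_DNA: bd_unlabelled(0.30, Medium.CSCL_DNA),
}


@dataclasses.dataclass(frozen=True)
class CarbonMetabolite:
    """A metabolite as an ordered list of per-carbon 13C probabilities."""

    name: str
    carbons: tuple[float, ...]

    def __init__(self, name: str, carbons):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "carbons", tuple(float(c) for c in carbons))
        if not self.carbons:
            raise DomainError(f"{name}: metabolite needs at least one carbon")
        if any(not (0.0 <= c <= 1.0) for c in self.carbons):
            raise DomainError(f"{name}: label probabilities must lie in [0, 1]")

    @property
    def n_carbons(self) -> int:
        return len(self.carbons)

    @property
    def mean_label(self) -> float:
        """Mean per-carbon 13C probability = the molecule's atom fraction."""
        return sum(self.carbons) / len(self.carbons)

    @property
    def label_sum(self) -> float:
        return sum(self.carbons)


class Substrate(str, enum.Enum):
    """Organic-carbon regime of an incubation."""

    UNLABELLED_POLYMER = "unlabelled_polymer"  # mixotrophy: organic C + DIC
    LABELLED_LACTATE = "labelled_lactate"
    NONE_AUTOTROPHIC = "none_autotrophic"  # all carbon from DIC


@dataclasses.dataclass(frozen=True)
class Scenario:
    """An incubation's carbon sources for nucleic-acid synthesis."""

    organic_substrate: Substrate
    dic_label: float = 0.0
    lactate_label: float = 0.99  # per-carbon 13C of amended lactate

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "organic_substrate", Substrate(self.organic_substrate)
        )
        for name in ("dic_label", "lactate_label"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1], got {v}")


def _require_carbons(m: CarbonMetabolite, n: int) -> None:
    if m.n_carbons != n:
        raise DomainError(f"{m.name}: expected {n} carbons, got {m.n_carbons}")


def carboxylate(acetyl: CarbonMetabolite, dic_label: float) -> CarbonMetabolite:
    """Pyruvate synthesis: acetyl-CoA (2C) + one CO2 from the DIC pool.

    The incorporated carboxyl carbon carries the DIC pool's 13C
    probability and is placed first (C1)."""
    _require_carbons(acetyl, 2)
    if not (0.0 <= dic_label <= 1.0):
        raise DomainError("dic_label must lie in [0, 1]")
    return CarbonMetabolite("pyruvate", (dic_label,) + acetyl.carbons)


def lactate_to_pyruvate(lactate: CarbonMetabolite) -> CarbonMetabolite:
    """Lactate oxidation to pyruvate: labels preserved position-wise."""
    _require_carbons(lactate, 3)
    return CarbonMetabolite("pyruvate", lactate.carbons)


def ribose_from_pyruvate(
    pyruvate: CarbonMetabolite,
    partner_triose: CarbonMetabolite,
    formaldehyde_position: int = 1,
) -> CarbonMetabolite:
    """Ribose via hexulose condensation and formaldehyde cleavage.

    Two three-carbon units condense into arabino-3-hexulose-6-phosphate
    (carbons of ``pyruvate`` first, then ``partner_triose``); the carbon
    at ``formaldehyde_position`` (0-based index in the hexulose) leaves
    as formaldehyde and the remaining five carbons form ribose.  The
    default position is an acetyl-derived (organic) carbon, so in the
    mixotrophic scenario the cleaved carbon is unlabelled and the DIC
    label is concentrated in the pentose.
    """
    _require_carbons(pyruvate, 3)
    _require_carbons(partner_triose, 3)
    hexulose = pyruvate.carbons + partner_triose.carbons
    if not 0 <= formaldehyde_position < 6:
        raise DomainError("formaldehyde_position must index a hexulose carbon")
    ribose = (
        hexulose[:formaldehyde_position] + hexulose[formaldehyde_position + 1:]
    )
    return CarbonMetabolite("ribose", ribose)


def predict_ribose_label(scenario: Scenario) -> float:
    """Predicted 13C atom fraction of nucleic-acid ribose.

    Mixotrophy on unlabelled polymers with DIC at label d gives 2d/5
    (two of five ribose carbons DIC-derived); labelled lactate carries
    its own per-carbon label through unchanged; the autotrophic route
    labels every carbon at d.
    """
    d = scenario.dic_label
    if scenario.organic_substrate is Substrate.UNLABELLED_POLYMER:
        acetyl = CarbonMetabolite("acetyl-CoA", (0.0, 0.0))
        pyr = carboxylate(acetyl, d)
        return ribose_from_pyruvate(pyr, pyr).mean_label
    if scenario.organic_substrate is Substrate.LABELLED_LACTATE:
        lac = CarbonMetabolite("lactate", (scenario.lactate_label,) * 3)
        pyr = lactate_to_pyruvate(lac)
        return ribose_from_pyruvate(pyr, pyr).mean_label
    # autotrophic: every precursor carbon drawn from the DIC pool
    pyr = CarbonMetabolite("pyruvate", (d, d, d))
    return ribose_from_pyruvate(pyr, pyr).mean_label


def predicted_density_class(
    atom_fraction: float,
    medium: Medium | str,
    cal: CalibrationResult,
    unlabelled_bd: float | None = None,
) -> Status:
    """Bin a predicted atom fraction into the classifier's density grades.

    The expected band center is a typical unlabelled buoyant density for
    the medium (override with ``unlabelled_bd``) plus the linear isotopic
    shift; it is compared with the calibration's threshold and strong
    densities."""
    medium = Medium.parse(medium)
    if unlabelled_bd is None:
        unlabelled_bd = TYPICAL_UNLABELLED_BD[medium]
    center = unlabelled_bd + density_shift(atom_fraction, medium)
    if center < cal.threshold_density:
        return Status.UNLABELLED
    if center < cal.strong_density:
        return Status.PARTIALLY_LABELLED
    return Status.STRONGLY_LABELLED


def predicted_band_shift(atom_fraction: float, medium: Medium | str) -> float:
    """Convenience re-export of the linear density shift (g/ml)."""
    return density_shift(atom_fraction, medium)


# ----------------------------------------------------------------------
# δ13C (‰ vs VPDB) <-> atom fraction, and TOC mixing
# ----------------------------------------------------------------------

def delta_to_atom_fraction(delta13c: float) -> float:
    """Convert δ13C (‰ vs VPDB) to the 13C atom fraction.

    R = R_VPDB · (1 + δ/1000); atom fraction = R / (1 + R).
    """
    if delta13c <= -1000.0:
        raise DomainError("delta13c must exceed -1000 permil")
    r = R_VPDB * (1.0 + delta13c / 1000.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(atom_fraction: float) -> float:
    """Inverse of :func:`delta_to_atom_fraction`."""
    if not (0.0 <= atom_fraction < 1.0):
        raise DomainError("atom_fraction must lie in [0, 1)")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / R_VPDB - 1.0) * 1000.0


def mix_toc(delta_old: float, f_new: float, af_new: float) -> float:
    """δ13C of a TOC pool after adding newly synthesized biomass.

    Two-pool isotope mass balance on atom fractions: a fraction
    ``f_new`` of the pool's carbon is new biomass at atom fraction
    ``af_new``, the rest keeps the old composition ``delta_old`` (‰).
    Returns the mixed pool's δ13C in ‰.
    """
    if not (0.0 <= f_new <= 1.0):
        raise DomainError("f_new must lie in [0, 1]")
    af = (1.0 - f_new) * delta_to_atom_fraction(delta_old) + f_new * af_new
    return atom_fraction_to_delta(af)
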