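"""Buoyant-density physics and the synthetic gradient simulator.

The model: a nucleic-acid species bands at an equilibrium buoyant density
(BD) set by its base composition (DNA in CsCl: the Schildkraut relation
BD = 1.660 + 0.098·GC g/ml; rRNA in CsTFA: an essentially GC-independent
baseline, 1.780 g/ml by default, because rRNA GC spans only ~50-60 mol%)
plus a shift proportional to its 13C atom fraction, up to a full-label
maximum of 0.036 g/ml (DNA) or 0.035 g/ml (RNA).  The band is Gaussian
with spread ``band_sigma`` and is discretized over 13 fraction bins whose
edges are midpoints between consecutive fraction densities, open-ended at
both tails.

Sequencing a fraction is modelled as a multinomial draw at fixed read
depth over the taxa's within-fraction mass shares; fractions whose total
nucleic-acid mass falls below ``template_floor`` yield no data at all
(library preparation fails), which the output marks as missing.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from nasip.errors import DomainError, NasipError
from nasip.fractions import FractionTable


class Medium(str, enum.Enum):
    """Gradient medium / nucleic-acid type."""

    CSCL_DNA = "dna"
    CSTFA_RNA = "rna"

    @classmethod
    def parse(cls, value: "Medium | str") -> "Medium":
        if isinstance(value, Medium):
            return value
        v = str(value).strip().lower()
        aliases = {
            "dna": cls.CSCL_DNA,
            "cscl": cls.CSCL_DNA,
            "cscl_dna": cls.CSCL_DNA,
            "rna": cls.CSTFA_RNA,
            "cstfa": cls.CSTFA_RNA,
            "cstfa_rna": cls.CSTFA_RNA,
        }
        if v not in aliases:
            raise DomainError(f"unknown medium {value!r}; use 'rna' or 'dna'")
        return aliases[v]


# Physics defaults, all g/ml.  DNA follows Schildkraut's CsCl relation;
# the RNA baseline is constant because rRNA GC varies too little to move
# the band appreciably.  Full-label shifts are literature-typical maxima
# for 100% 13C substitution.
DNA_BD_INTERCEPT = 1.660
DNA_BD_GC_SLOPE = 0.098
RNA_BD_BASELINE = 1.780
MAX_SHIFT = {Medium.CSCL_DNA: 0.036, Medium.CSTFA_RNA: 0.035}

#: Default 13-fraction density grids, heaviest fraction first.
DEFAULT_GRID = {
    Medium.CSTFA_RNA: tuple(np.linspace(1.830, 1.750, 13)),
    Medium.CSCL_DNA: tuple(np.linspace(1.740, 1.660, 13)),
}


def _check_fraction(name: str, x: float) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0) or math.isnan(x):
        raise DomainError(f"{name} must lie in [0, 1], got {x}")
    return x


@dataclasses.dataclass(frozen=True)
class Taxon:
    """A community member.

    ``gc`` is G+C mol% / 100 of its nucleic acid, ``abundance`` its
    community proportion, ``atom_fraction_13c`` the proportion of its
    nucleic-acid carbon that is 13C.
    """

    taxon_id: str
    gc: float
    abundance: float
    atom_fraction_13c: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction("gc", self.gc)
        _check_fraction("abundance", self.abundance)
        _check_fraction("atom_fraction_13c", self.atom_fraction_13c)


@dataclasses.dataclass(frozen=True)
class GradientSpec:
    """Geometry and sampling parameters of one simulated gradient."""

    medium: Medium
    fraction_densities: tuple[float, ...] = ()
    band_sigma: float = 0.004
    read_depth: int = 50_000
    template_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "medium", Medium.parse(self.medium))
        dens = tuple(float(d) for d in self.fraction_densities) or DEFAULT_GRID[
            self.medium
        ]
        object.__setattr__(self, "fraction_densities", dens)
        if len(dens) != 13:
            raise DomainError(f"expected 13 fraction densities, got {len(dens)}")
        if not all(a > b for a, b in zip(dens, dens[1:])):
            raise DomainError("fraction densities must be strictly decreasing")
        if not self.band_sigma > 0:
            raise DomainError("band_sigma must be positive")
        if self.read_depth < 1:
            raise DomainError("read_depth must be >= 1")

    @property
    def fraction_ids(self) -> list[str]:
        return [f"F{i}" for i in range(1, len(self.fraction_densities) + 1)]

    def bin_edges(self) -> np.ndarray:
        """Density interval edges per fraction, from +inf (above the
        heaviest fraction) down to -inf, via midpoints between fractions."""
        d = np.asarray(self.fraction_densities)
        mids = (d[:-1] + d[1:]) / 2.0
        return np.concatenate(([np.inf], mids, [-np.inf]))


@dataclasses.dataclass(frozen=True)
class BandProfile:
    """A taxon's band mass discretized over the fraction bins."""

    taxon_id: str
    per_fraction_mass: tuple[float, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.per_fraction_mass)
        if (m < 0).any():
            raise DomainError("band masses must be non-negative")
        if m.sum() > 1 + 1e-9:
            raise DomainError("band masses must sum to <= 1")


def bd_unlabelled(
    gc: float,
    medium: Medium | str,
    *,
    dna_intercept: float = DNA_BD_INTERCEPT,
    dna_gc_slope: float = DNA_BD_GC_SLOPE,
    rna_baseline: float = RNA_BD_BASELINE,
    rna_gc_slope: float = 0.0,
) -> float:
    """Buoyant density (g/ml) of unlabelled nucleic acid of the given GC.

    CsCl DNA uses the linear Schildkraut map; CsTFA RNA uses a constant
    baseline by default, with an optional weak GC slope anchored at
    GC = 0.55 (the middle of the rRNA range).
    """
    gc = _check_fraction("gc", gc)
    medium = Medium.parse(medium)
    if medium is Medium.CSCL_DNA:
        return dna_intercept + dna_gc_slope * gc
    return rna_baseline + rna_gc_slope * (gc - 0.55)


def density_shift(atom_fraction_13c: float, medium: Medium | str) -> float:
    """Band-density increase (g/ml) caused by 13C substitution.

    Linear in the atom fraction, reaching ``MAX_SHIFT[medium]`` at full
    labelling; heavier banding therefore reports a higher degree of
    labelling.
    """
    af = _check_fraction("atom_fraction_13c", atom_fraction_13c)
    return af * MAX_SHIFT[Medium.parse(medium)]


def band_center(taxon: Taxon, medium: Medium | str, **bd_kwargs) -> float:
    """Equilibrium band center: unlabelled BD plus the isotopic shift."""
    medium = Medium.parse(medium)
    return bd_unlabelled(taxon.gc, medium, **bd_kwargs) + density_shift(
        taxon.atom_fraction_13c, medium
    )


def band_profile(taxon: Taxon, spec: GradientSpec, **bd_kwargs) -> BandProfile:
    """Integrate the taxon's Gaussian band over each fraction's interval."""
    mu = band_center(taxon, spec.medium, **bd_kwargs)
    edges = spec.bin_edges()
    cdf = norm.cdf(edges, loc=mu, scale=spec.band_sigma)
    mass = cdf[:-1] - cdf[1:]  # edges run heavy -> light
    mass = np.clip(mass, 0.0, None)
    return BandProfile(taxon.taxon_id, tuple(mass))


def _mass_matrix(community: Sequence[Taxon], spec: GradientSpec, **bd_kwargs):
    m = np.array(
        [
            np.asarray(band_profile(t, spec, **bd_kwargs).per_fraction_mass)
            * t.abundance
            for t in community
        ]
    )
    return m


def simulate_gradient(
    community: Sequence[Taxon],
    spec: GradientSpec,
    *,
    scale: bool = True,
    **bd_kwargs,
) -> FractionTable:
    """Simulate sequencing of one gradient's fractions.

    Per fraction, expected taxon proportions are abundance-weighted band
    masses renormalized within the fraction; observed counts are a
    multinomial draw of ``spec.read_depth`` reads.  Fractions whose total
    nucleic-acid mass is below ``spec.template_floor`` are marked missing.
    Returns a total-sum-scaled table by default, raw counts with
    ``scale=False``.
    """
    if not community:
        raise NasipError("empty community")
    ab = np.array([t.abundance for t in community])
    if abs(ab.sum() - 1.0) > 1e-9:
        raise DomainError(f"community abundances sum to {ab.sum()}, expected 1")
    ids = [t.taxon_id for t in community]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate taxon ids in community")

    rng = np.random.default_rng(spec.seed)
    mass = _mass_matrix(community, spec, **bd_kwargs)  # taxa x fractions
    totals = mass.sum(axis=0)
    n_frac = len(spec.fraction_densities)
    counts = np.full((len(community), n_frac), np.nan)
    missing = totals < spec.template_floor
    for j in range(n_frac):
        if missing[j]:
            continue
        p = mass[:, j] / totals[j]
        counts[:, j] = rng.multinomial(spec.read_depth, p)
    values = pd.DataFrame(
        counts, index=pd.Index(ids, name="otu_id"), columns=spec.fraction_ids
    )
    table = FractionTable(
        values,
        pd.Series(spec.fraction_densities, index=spec.fraction_ids),
        pd.Series(missing, index=spec.fraction_ids),
        medium=spec.medium.value,
        scaled=False,
    )
    if scale:
        from nasip.fractions import total_sum_scale

        table = total_sum_scale(table)
    return table


def simulate_standards(
    spec: GradientSpec,
    gc_standard: float = 0.51,
    label_high: float = 0.99,
    **bd_kwargs,
) -> tuple[FractionTable, FractionTable]:
    """Simulate the unlabelled / fully-labelled calibration standards.

    Each standard is a single nucleic-acid species (default GC 0.51, the
    E. coli value) quantified across the gradient: reads are distributed
    over fractions in proportion to band mass, so the table records the
    standard's mass profile rather than within-fraction composition.
    Returns ``(unlabelled, labelled)`` as unscaled single-row tables.
    """
    if not (0.0 <= label_high <= 1.0):
        raise DomainError("label_high must lie in [0, 1]")
    tables = []
    for offset, (name, af) in enumerate(
        [("std_unlabelled", 0.0), ("std_labelled", label_high)]
    ):
        taxon = Taxon(name, gc=gc_standard, abundance=1.0, atom_fraction_13c=af)
        mass = np.asarray(band_profile(taxon, spec, **bd_kwargs).per_fraction_mass)
        rng = np.random.default_rng(spec.seed + offset)
        counts = rng.multinomial(spec.read_depth, mass / mass.sum()).astype(float)
        values = pd.DataFrame(
            [counts], index=pd.Index([name], name="otu_id"), columns=spec.fraction_ids
        )
        tables.append(
            FractionTable(
                values,
                pd.Series(spec.fraction_densities, index=spec.fraction_ids),
                pd.Series(False, index=spec.fraction_ids),
                medium=spec.medium.value,
                scaled=False,
            )
        )
    return tables[0], tables[1]


def expected_proportions(
    community: Sequence[Taxon], spec: GradientSpec, **bd_kwargs
) -> pd.DataFrame:
    """Noise-free within-fraction taxon proportions (taxa x fractions).

    Fractions below the template floor hold NaN, mirroring
    :func:`simulate_gradient`'s missing fractions."""
    mass = _mass_matrix(community, spec, **bd_kwargs)
    totals = mass.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals >= spec.template_floor, mass / totals, np.nan)
    return pd.DataFrame(
        p, index=[t.taxon_id for t in community], columns=spec.fraction_ids
    )


def reference_community(labelled: bool = True) -> list[Taxon]:
    """The default benchmark community for DNA-SIP simulations.

    Ten taxa spanning the low-GC range typical of sediment archaea
    (GC 0.28-0.40, so no unlabelled member reaches the CsCl heavy
    window): six unlabelled, two partially labelled (13C atom fraction
    0.4, the mixotrophic signature) and two fully labelled (1.0).  With
    ``labelled=False`` the same community is returned with all atom
    fractions zeroed — the parallel control incubation.
    """
    rows = [
        ("u1", 0.28, 0.20, 0.0),
        ("u2", 0.30, 0.15, 0.0),
        ("u3", 0.32, 0.12, 0.0),
        ("u4", 0.35, 0.10, 0.0),
        ("u5", 0.40, 0.05, 0.0),
        ("u6", 0.34, 0.08, 0.0),
        ("p1", 0.30, 0.08, 0.4),
        ("p2", 0.33, 0.06, 0.4),
        ("s1", 0.29, 0.10, 1.0),
        ("s2", 0.31, 0.06, 1.0),
    ]
    return [
        Taxon(tid, gc, ab, af if labelled else 0.0) for tid, gc, ab, af in rows
    ]


#: Ground-truth status per reference-community taxon when classified
#: against the unlabelled control (fixed DNA thresholds).
REFERENCE_TRUTH = {
    "u1": "unlabelled", "u2": "unlabelled", "u3": "unlabelled",
    "u4": "unlabelled", "u5": "unlabelled", "u6": "unlabelled",
    "p1": "partially_labelled", "p2": "partially_labelled",
    "s1": "strongly_labelled", "s2": "strongly_labelled",
}


def write_taxa_manifest(community: Sequence[Taxon], path) -> None:
    """Tab-separated taxon manifest: id, gc, abundance, atom_fraction_13c."""
    pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t in community],
            "gc": [t.gc for t in community],
            "abundance": [t.abundance for t in community],
            "atom_fraction_13c": [t.atom_fraction_13c for t in community],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_taxa_manifest(path) -> list[Taxon]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    return [
        Taxon(r.taxon_id, float(r.gc), float(r.abundance), float(r.atom_fraction_13c))
        for r in df.itertuples()
    ]
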