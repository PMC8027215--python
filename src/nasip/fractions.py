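"""OTU-by-fraction tables: I/O, pooling, and total-sum scaling.

A :class:`FractionTable` holds one isopycnic gradient: OTU rows, fraction
columns, a buoyant density per fraction, and an explicit missing flag for
fractions that yielded no sequence data (e.g. cDNA synthesis failed from
insufficient template).  Fractions are ordered heaviest first — fraction 1
is drawn from the bottom of the gradient.

Missing data are never encoded as zeros: a zero means "OTU not detected in
a sequenced fraction", a missing column means "fraction not sequenced".
Tables carry raw counts until :func:`total_sum_scale` converts them to
per-fraction relative abundances; pooling must happen on the raw counts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from nasip.errors import TableFormatError

_DENSITY_TOL = 1e-12


@dataclasses.dataclass
class FractionTable:
    """One gradient's OTU abundances across density fractions.

    Parameters
    ----------
    values
        DataFrame indexed by OTU id, one column per fraction id.  Missing
        fractions hold NaN in every row.
    densities
        Buoyant density (g/ml) per fraction id, strictly decreasing in
        column order (fraction 1 = heaviest).
    missing
        Boolean per fraction id; True means the fraction yielded no data.
    medium
        Free-form medium tag, conventionally ``"rna"`` (CsTFA) or
        ``"dna"`` (CsCl).
    scaled
        Whether columns are total-sum-scaled relative abundances.
    """

    values: pd.DataFrame
    densities: pd.Series
    missing: pd.Series
    medium: str = ""
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.densities = pd.Series(self.densities, dtype=float)
        self.missing = pd.Series(self.missing, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            raise TableFormatError("duplicate fraction ids")
        if list(self.densities.index) != cols or list(self.missing.index) != cols:
            raise TableFormatError(
                "density/missing metadata must cover exactly the table's fractions, "
                "in column order"
            )
        otus = list(self.values.index)
        dupes = {o for o in otus if otus.count(o) > 1}
        if dupes:
            raise TableFormatError(f"duplicate OTU ids: {sorted(dupes)}")
        d = self.densities.to_numpy()
        if len(d) > 1 and not np.all(np.diff(d) < -_DENSITY_TOL):
            raise TableFormatError(
                "fraction densities must be strictly decreasing (fraction 1 heaviest)"
            )
        # missing columns carry no values; enforce NaN there
        for fid, miss in self.missing.items():
            if miss:
                self.values[fid] = np.nan
            elif self.values[fid].isna().any():
                raise TableFormatError(
                    f"non-missing fraction {fid!r} contains NaN values"
                )

    # -- conveniences -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.values.index]

    @property
    def fraction_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def present_fractions(self) -> list[str]:
        return [f for f in self.fraction_ids if not self.missing[f]]

    def abundance(self, otu_id: str, fraction_id: str) -> float:
        return float(self.values.at[otu_id, fraction_id])

    def copy(self) -> "FractionTable":
        return FractionTable(
            self.values.copy(),
            self.densities.copy(),
            self.missing.copy(),
            self.medium,
            self.scaled,
        )

    def equals(self, other: "FractionTable", tol: float = 1e-12) -> bool:
        if self.fraction_ids != other.fraction_ids or self.otu_ids != other.otu_ids:
            return False
        if not np.allclose(self.densities, other.densities, atol=tol):
            return False
        if not self.missing.equals(other.missing):
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return bool(np.allclose(a, b, atol=tol, equal_nan=True))


@dataclasses.dataclass(frozen=True)
class PoolingScheme:
    """Disjoint groups of fraction ids to be combined before sequencing."""

    groups: tuple[tuple[str, ...], ...]

    def __init__(self, groups: Iterable[Sequence[str]]):
        object.__setattr__(
            self, "groups", tuple(tuple(str(f) for f in g) for g in groups)
        )
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise TableFormatError("empty pooling group")
            for f in g:
                if f in seen:
                    raise TableFormatError(f"fraction {f!r} appears in two groups")
                seen.add(f)


def rna_pairwise_pooling(fraction_ids: Sequence[str]) -> PoolingScheme:
    """The RNA-SIP sequencing layout: fractions 4+5, 6+7, 8+9 and 10+11
    combined pairwise; all other fractions sequenced individually."""
    ids = [str(f) for f in fraction_ids]
    if len(ids) < 11:
        raise TableFormatError("pairwise pooling needs at least 11 fractions")
    groups = [[ids[0]], [ids[1]], [ids[2]]]
    groups += [[ids[3], ids[4]], [ids[5], ids[6]], [ids[7], ids[8]], [ids[9], ids[10]]]
    groups += [[f] for f in ids[11:]]
    return PoolingScheme(groups)


# ----------------------------------------------------------------------
# I/O: tab-separated OTU table plus sidecar fraction metadata
# ----------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".fractions.tsv")


def write_table(table: FractionTable, path: str | Path) -> None:
    """Write a table as TSV plus a ``<name>.fractions.tsv`` sidecar.

    The main file has an ``otu_id`` first column and one column per
    fraction; missing fractions are written as ``NA``.  The sidecar lists
    fraction_id, density (g/ml), missing flag, medium and the scaled flag.
    """
    path = Path(path)
    out = table.values.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
    meta = pd.DataFrame(
        {
            "fraction_id": table.fraction_ids,
            "density": [table.densities[f] for f in table.fraction_ids],
            "missing": [int(table.missing[f]) for f in table.fraction_ids],
            "medium": table.medium,
            "scaled": int(table.scaled),
        }
    )
    meta.to_csv(_sidecar_path(path), sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path, sidecar: str | Path | None = None) -> FractionTable:
    """Read a table written by :func:`write_table`.

    Raises :class:`TableFormatError` with a line-numbered message on
    duplicate OTU ids, non-numeric cells, or a sidecar whose fractions do
    not match the table header.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not path.exists():
        raise TableFormatError(f"no such table file: {path}")
    if not sidecar.exists():
        raise TableFormatError(f"missing fraction-metadata sidecar: {sidecar}")

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "otu_id":
        raise TableFormatError(f"{path}:1: first column must be 'otu_id'")
    fraction_ids = header[1:]
    otus: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        otu = cells[0]
        if otu in seen:
            raise TableFormatError(f"{path}:{lineno}: duplicate OTU id {otu!r}")
        seen.add(otu)
        vals = []
        for col, cell in zip(fraction_ids, cells[1:]):
            if cell in ("NA", ""):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in fraction {col!r}"
                ) from None
        otus.append(otu)
        rows.append(vals)

    meta = pd.read_csv(sidecar, sep="\t", dtype={"fraction_id": str})
    required = {"fraction_id", "density", "missing"}
    if not required.issubset(meta.columns):
        raise TableFormatError(f"{sidecar}: needs columns {sorted(required)}")
    if list(meta["fraction_id"]) != fraction_ids:
        raise TableFormatError(
            f"{sidecar}: fraction ids {list(meta['fraction_id'])} do not match "
            f"table header {fraction_ids}"
        )
    if meta["density"].isna().any():
        bad = meta.loc[meta["density"].isna(), "fraction_id"].tolist()
        raise TableFormatError(f"{sidecar}: missing density for fractions {bad}")

    values = pd.DataFrame(rows, index=pd.Index(otus, name="otu_id"),
                          columns=fraction_ids)
    medium = str(meta["medium"].iloc[0]) if "medium" in meta else ""
    scaled = bool(int(meta["scaled"].iloc[0])) if "scaled" in meta else False
    return FractionTable(
        values,
        pd.Series(meta["density"].to_numpy(), index=fraction_ids),
        pd.Series(meta["missing"].astype(bool).to_numpy(), index=fraction_ids),
        medium=medium,
        scaled=scaled,
    )


# ----------------------------------------------------------------------
# Pooling and normalization
# ----------------------------------------------------------------------

def pool_fractions(table: FractionTable, scheme: PoolingScheme) -> FractionTable:
    """Combine groups of fractions into single columns.

    Pooled values are the sums of the member columns (hence pooling must
    precede total-sum scaling); the pooled density is the arithmetic mean
    of member densities.  A group containing any missing member is pooled
    to a missing column.  Fractions not named in any group pass through
    unchanged; output columns keep density order.
    """
    if table.scaled:
        raise TableFormatError(
            "pooling requires raw counts; pool before total_sum_scale"
        )
    known = set(table.fraction_ids)
    for g in scheme.groups:
        for f in g:
            if f not in known:
                raise TableFormatError(f"unknown fraction id in pooling scheme: {f!r}")
    grouped = {f: g for g in scheme.groups for f in g}
    new_cols: list[str] = []
    new_vals: dict[str, np.ndarray] = {}
    new_dens: dict[str, float] = {}
    new_miss: dict[str, bool] = {}
    done: set[tuple[str, ...]] = set()
    for fid in table.fraction_ids:
        if fid not in grouped:
            new_cols.append(fid)
            new_vals[fid] = table.values[fid].to_numpy()
            new_dens[fid] = float(table.densities[fid])
            new_miss[fid] = bool(table.missing[fid])
            continue
        g = grouped[fid]
        if g in done:
            continue
        done.add(g)
        name = g[0] if len(g) == 1 else "+".join(g)
        new_cols.append(name)
        new_dens[name] = float(np.mean([table.densities[f] for f in g]))
        if any(table.missing[f] for f in g):
            new_miss[name] = True
            new_vals[name] = np.full(len(table.otu_ids), np.nan)
        else:
            new_miss[name] = False
            new_vals[name] = sum(table.values[f].to_numpy() for f in g)
    values = pd.DataFrame(
        {c: new_vals[c] for c in new_cols},
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
    return FractionTable(
        values,
        pd.Series([new_dens[c] for c in new_cols], index=new_cols),
        pd.Series([new_miss[c] for c in new_cols], index=new_cols),
        medium=table.medium,
        scaled=False,
    )


def total_sum_scale(table: FractionTable) -> FractionTable:
    """Divide each non-missing column by its sum (per-fraction relative
    abundance).  All-zero columns become missing; negative values raise."""
    vals = table.values.copy()
    arr = vals.to_numpy()
    if np.nanmin(arr, initial=0.0) < 0:
        raise TableFormatError("negative abundance value")
    missing = table.missing.copy()
    for fid in table.fraction_ids:
        if missing[fid]:
            continue
        s = vals[fid].sum()
        if s <= 0:
            missing[fid] = True
            vals[fid] = np.nan
        else:
            vals[fid] = vals[fid] / s
    return FractionTable(
        vals, table.densities.copy(), missing, medium=table.medium, scaled=True
    )
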