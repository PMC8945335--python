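"""Data model and file I/O for dominant binary marker matrices.

Dominant multilocus fingerprints (ISSR, AFLP, RAPD) are scored per
individual and locus as band presence (1) or absence (0).  The
:class:`MarkerMatrix` is the universal input of every statistic in this
package: an individuals x loci 0/1 table plus a population label per
individual and, optionally, planar coordinates per population.

Three text dialects are supported: a plain CSV, a minimal GenAlEx binary
layout, and a STRUCTURE-style one-row-per-individual dominant file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MarkerMatrix",
    "PopulationGeo",
    "read_matrix",
    "write_matrix",
]

#: Reserved sentinel for declared-missing cells.  The study pipeline assumes
#: complete data, so every statistics module rejects matrices containing it.
MISSING = -9

_DIALECTS = ("csv", "genalex", "structure")


class MatrixValidationError(ValueError):
    """A marker matrix violated a structural invariant."""


@dataclass
class MarkerMatrix:
    """Binary individuals x loci band table with population labels.

    Parameters
    ----------
    individual_ids
        Unique labels, one per row of ``bands``.
    locus_ids
        Unique labels, one per column of ``bands``.
    bands
        ``(n_individuals, n_loci)`` array over {0, 1} (``MISSING`` allowed
        only if explicitly declared via ``allow_missing``).
    pop_of
        Mapping individual label -> population label.
    """

    individual_ids: list
    locus_ids: list
    bands: np.ndarray
    pop_of: dict
    allow_missing: bool = False

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.bands = np.asarray(self.bands, dtype=np.int8)
        self.pop_of = {str(k): str(v) for k, v in self.pop_of.items()}
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        seen: dict = {}
        for ind in self.individual_ids:
            seen.setdefault(self.pop_of[ind], None)
        return list(seen)

    @property
    def pop_labels(self) -> np.ndarray:
        """Per-row population label array aligned with ``bands``."""
        return np.array([self.pop_of[i] for i in self.individual_ids])

    def pop_sizes(self) -> dict:
        labels = self.pop_labels
        return {p: int((labels == p).sum()) for p in self.populations}

    def has_missing(self) -> bool:
        return bool((self.bands == MISSING).any())

    def require_complete(self) -> None:
        """Raise if any cell is declared missing (statistics fail fast)."""
        if self.has_missing():
            raise MatrixValidationError(
                "matrix contains declared-missing cells; statistics for "
                "dominant data require a complete 0/1 matrix"
            )

    def validate(self) -> None:
        n, L = self.bands.shape
        if n != len(self.individual_ids):
            raise MatrixValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if L != len(self.locus_ids):
            raise MatrixValidationError(
                f"{len(self.locus_ids)} locus ids for {L} columns"
            )
        if len(set(self.individual_ids)) != n:
            raise MatrixValidationError("duplicate individual labels")
        if len(set(self.locus_ids)) != L:
            raise MatrixValidationError("duplicate locus labels")
        allowed = {0, 1} | ({MISSING} if self.allow_missing else set())
        bad = ~np.isin(self.bands, list(allowed))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary cell value {int(self.bands[i, j])} at "
                f"individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}"
            )
        missing_pop = [i for i in self.individual_ids if i not in self.pop_of]
        if missing_pop:
            raise MatrixValidationError(
                f"individuals without population: {missing_pop[:5]}"
            )
        if not self.populations:
            raise MatrixValidationError("no populations")

    # -- dataframe views ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: individual, population, one column per locus."""
        df = pd.DataFrame(self.bands, columns=self.locus_ids)
        df.insert(0, "population", [self.pop_of[i] for i in self.individual_ids])
        df.insert(0, "individual", self.individual_ids)
        return df

    def pop_band_counts(self) -> pd.DataFrame:
        """Populations x loci table of band-present counts."""
        self.require_complete()
        df = pd.DataFrame(self.bands, index=self.pop_labels, columns=self.locus_ids)
        return df.groupby(level=0, sort=False).sum().loc[self.populations]

    # -- subsetting --------------------------------------------------------

    def subset(self, keep_individuals=None, keep_populations=None) -> "MarkerMatrix":
        """Restrict to the named individuals or populations.

        Exactly one of the two selectors must be given.  The locus set is
        unchanged and invariants are re-validated.
        """
        if (keep_individuals is None) == (keep_populations is None):
            raise ValueError("give exactly one of keep_individuals/keep_populations")
        if keep_populations is not None:
            keep_populations = [str(p) for p in keep_populations]
            unknown = set(keep_populations) - set(self.populations)
            if unknown:
                raise KeyError(f"unknown populations: {sorted(unknown)}")
            keep = set(keep_populations)
            ids = [i for i in self.individual_ids if self.pop_of[i] in keep]
        else:
            keep_individuals = [str(i) for i in keep_individuals]
            unknown = set(keep_individuals) - set(self.individual_ids)
            if unknown:
                raise KeyError(f"unknown individuals: {sorted(unknown)}")
            keep = set(keep_individuals)
            ids = [i for i in self.individual_ids if i in keep]
        if not ids:
            raise ValueError("empty selection")
        idx = [self.individual_ids.index(i) for i in ids]
        return MarkerMatrix(
            individual_ids=ids,
            locus_ids=list(self.locus_ids),
            bands=self.bands[idx],
            pop_of={i: self.pop_of[i] for i in ids},
            allow_missing=self.allow_missing,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.bands, other.bands)
            and {i: self.pop_of[i] for i in self.individual_ids}
            == {i: other.pop_of[i] for i in other.individual_ids}
        )


@dataclass
class PopulationGeo:
    """Planar population coordinates in kilometres."""

    coords: dict = field(default_factory=dict)  # population -> (x_km, y_km)

    @classmethod
    def from_lonlat(cls, lonlat: dict) -> "PopulationGeo":
        """Project lon/lat degrees to planar km (equirectangular).

        Uses the mean latitude of the populations as the reference parallel;
        only relative distances matter downstream (the Mantel test works on
        log distances), so this small-area projection is adequate.
        """
        lat0 = math.radians(np.mean([ll[1] for ll in lonlat.values()]))
        R = 6371.0
        coords = {}
        for pop, (lon, lat) in lonlat.items():
            x = R * math.radians(lon) * math.cos(lat0)
            y = R * math.radians(lat)
            coords[str(pop)] = (x, y)
        return cls(coords)

    @property
    def populations(self) -> list:
        return list(self.coords)

    def distance_matrix(self, order=None) -> pd.DataFrame:
        """Pairwise Euclidean distances (km) as a labelled square frame."""
        pops = list(order) if order is not None else self.populations
        xy = np.array([self.coords[p] for p in pops], dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        off = d[~np.eye(len(pops), dtype=bool)]
        if len(pops) > 1 and (off <= 0).any():
            raise ValueError("distinct populations with zero separation")
        return pd.DataFrame(d, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# I/O dialects
# ---------------------------------------------------------------------------


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def read_matrix(path, dialect: str = "csv") -> MarkerMatrix:
    """Read a marker matrix from ``path`` under the named dialect."""
    _check_dialect(dialect)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "genalex":
        return _read_genalex(path)
    return _read_structure(path)


def write_matrix(m: MarkerMatrix, path, dialect: str = "csv") -> None:
    """Write ``m`` to ``path``; the file round-trips through read_matrix."""
    _check_dialect(dialect)
    if dialect == "csv":
        _write_csv(m, path)
    elif dialect == "genalex":
        _write_genalex(m, path)
    else:
        _write_structure(m, path)


def _parse_cell(tok: str, where: str):
    try:
        v = int(tok)
    except ValueError:
        raise MatrixValidationError(f"non-integer cell {tok!r} at {where}")
    return v


def _read_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise MatrixValidationError("csv needs individual, population, >=1 locus")
    ids = df.iloc[:, 0].astype(str).tolist()
    pops = df.iloc[:, 1].astype(str).tolist()
    loci = [str(c) for c in df.columns[2:]]
    bands = np.empty((len(ids), len(loci)), dtype=np.int8)
    for j, c in enumerate(df.columns[2:]):
        for i, tok in enumerate(df[c]):
            bands[i, j] = _parse_cell(tok, f"row {ids[i]!r}, column {c!r}")
    return MarkerMatrix(ids, loci, bands, dict(zip(ids, pops)))


def _write_csv(m: MarkerMatrix, path) -> None:
    m.to_frame().to_csv(path, index=False)


def _write_genalex(m: MarkerMatrix, path) -> None:
    # Minimal binary GenAlEx layout: numeric header row, title row with
    # population names, column header, then one data row per individual.
    pops = m.populations
    sizes = m.pop_sizes()
    with open(path, "w") as fh:
        fh.write(
            ",".join(
                [str(m.n_loci), str(m.n_individuals), str(len(pops))]
                + [str(sizes[p]) for p in pops]
            )
            + "\n"
        )
        fh.write(",".join(["binary dominant markers", ""] + pops) + "\n")
        fh.write(",".join(["Sample", "Pop"] + m.locus_ids) + "\n")
        for i, ind in enumerate(m.individual_ids):
            row = [ind, m.pop_of[ind]] + [str(int(v)) for v in m.bands[i]]
            fh.write(",".join(row) + "\n")


def _read_genalex(path) -> MarkerMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 4:
        raise MatrixValidationError("genalex file too short")
    head = lines[0].split(",")
    n_loci, n_ind = int(head[0]), int(head[1])
    header = lines[2].split(",")
    loci = header[2 : 2 + n_loci]
    ids, pops, rows = [], [], []
    for ln in lines[3 : 3 + n_ind]:
        parts = ln.split(",")
        ids.append(parts[0])
        pops.append(parts[1])
        rows.append(
            [
                _parse_cell(t, f"row {parts[0]!r}, column {loci[k]!r}")
                for k, t in enumerate(parts[2 : 2 + n_loci])
            ]
        )
    return MarkerMatrix(ids, loci, np.array(rows, dtype=np.int8), dict(zip(ids, pops)))


def _write_structure(m: MarkerMatrix, path) -> None:
    # One row per individual (dominant data): label, integer-recoded
    # population, then one 0/1 column per locus.  Comment lines preserve the
    # population names so the file round-trips losslessly.
    pops = m.populations
    code = {p: k + 1 for k, p in enumerate(pops)}
    with open(path, "w") as fh:
        for p in pops:
            fh.write(f"#pop {code[p]} {p}\n")
        fh.write("\t".join(m.locus_ids) + "\n")
        for i, ind in enumerate(m.individual_ids):
            row = [ind, str(code[m.pop_of[ind]])] + [str(int(v)) for v in m.bands[i]]
            fh.write("\t".join(row) + "\n")


def _read_structure(path) -> MarkerMatrix:
    names: dict = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#pop "):
            _, code, name = ln.split(" ", 2)
            names[code] = name
        else:
            body.append(ln)
    if not body:
        raise MatrixValidationError("empty structure file")
    loci = body[0].split("\t")
    ids, pops, rows = [], [], []
    for ln in body[1:]:
        parts = ln.split("\t")
        ids.append(parts[0])
        pops.append(names.get(parts[1], parts[1]))
        rows.append(
            [
                _parse_cell(t, f"row {parts[0]!r}, column {loci[k]!r}")
                for k, t in enumerate(parts[2:])
            ]
        )
    return MarkerMatrix(ids, loci, np.array(rows, dtype=np.int8), dict(zip(ids, pops)))
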