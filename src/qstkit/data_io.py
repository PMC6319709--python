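"""Input/output for genotype, trait, soil and coordinate tables.

Genotypes are codominant diploid microsatellite calls (integer fragment
lengths) carried in a :class:`GenotypeTable`.  Two text dialects are
supported: a GenAlEx-style CSV (two columns per locus) and the STRUCTURE
two-row-per-individual whitespace format.  Trait, soil and coordinate data
travel as plain :class:`pandas.DataFrame` objects with documented column
names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Internal sentinel for a missing allele slot.
MISSING = -1

#: Allele codes accepted as "missing" on input (the two dialects disagree).
MISSING_INPUT_CODES = (0, -9)

#: Mean Earth radius in km (IUGG), used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0088

#: Soil points within this great-circle radius of a population are averaged.
DEFAULT_SOIL_RADIUS_KM = 15.0

TREATMENTS = ("T0", "T70", "T150")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


@dataclass
class GenotypeTable:
    """Individuals x loci codominant diploid genotypes with population labels.

    Parameters
    ----------
    individuals : list of str
        Unique individual identifiers, one per row of ``alleles``.
    populations : list of str
        Population label per individual (parallel to ``individuals``).
    loci : list of str
        Locus names, one per slice of ``alleles``.
    alleles : ndarray of int, shape (n_individuals, n_loci, 2)
        Integer allele codes (fragment lengths); :data:`MISSING` marks a
        missing slot.  Missingness is per-individual, per-locus (both slots).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n_ind, n_loc = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n_ind, n_loc, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"({n_ind}, {n_loc}, 2)"
            )
        if len(self.populations) != n_ind:
            raise ValueError("populations must be parallel to individuals")
        if len(set(self.individuals)) != n_ind:
            dupes = pd.Series(self.individuals)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise GenotypeParseError(f"duplicate individual ids: {dupes}")
        # a half-missing genotype cannot be phased into frequencies; drop both
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            self.alleles = self.alleles.copy()
            self.alleles[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing genotypes."""
        return (self.alleles == MISSING).all(axis=2)

    def subset(
        self,
        populations: list[str] | None = None,
        individuals: list[str] | None = None,
    ) -> "GenotypeTable":
        """Return a new table restricted to the given populations/individuals."""
        keep = np.ones(self.n_individuals, dtype=bool)
        if populations is not None:
            popset = set(populations)
            keep &= np.array([p in popset for p in self.populations])
        if individuals is not None:
            indset = set(individuals)
            keep &= np.array([i in indset for i in self.individuals])
        idx = np.flatnonzero(keep)
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.loci),
            self.alleles[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-ish frame: one row per individual, two columns per locus."""
        data = {"individual_id": self.individuals, "population_id": self.populations}
        for j, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.alleles[:, j, 0]
            data[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(data)


def _normalize_missing(a: np.ndarray) -> np.ndarray:
    a = a.copy()
    for code in MISSING_INPUT_CODES:
        a[a == code] = MISSING
    return a


# ---------------------------------------------------------------------------
# GenAlEx-style CSV
# ---------------------------------------------------------------------------

def _read_genalex(path: Path) -> GenotypeTable:
    with open(path, "r", newline="") as fh:
        rows = [line.rstrip("\n").split(",") for line in fh]
    if len(rows) < 4:
        raise GenotypeParseError(f"{path}: fewer than 4 lines; not GenAlEx CSV")
    try:
        n_loci = int(rows[0][0])
        n_ind = int(rows[0][1])
    except (ValueError, IndexError) as exc:
        raise GenotypeParseError(f"{path} line 1: expected n_loci,n_individuals,...") from exc
    header = rows[2]
    loci = [header[2 + 2 * j].strip() for j in range(n_loci)]
    individuals: list[str] = []
    populations: list[str] = []
    alleles = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n_ind):
        lineno = 4 + i
        row = rows[3 + i]
        expected = 2 + 2 * n_loci
        if len([c for c in row if c != ""]) < 2:
            raise GenotypeParseError(f"{path} line {lineno}: blank/short row")
        if len(row) < expected:
            raise GenotypeParseError(
                f"{path} line {lineno}: {len(row)} fields, expected {expected}"
            )
        individuals.append(row[0].strip())
        populations.append(row[1].strip())
        for j in range(n_loci):
            for k in range(2):
                cell = row[2 + 2 * j + k].strip()
                try:
                    alleles[i, j, k] = int(cell) if cell else MISSING
                except ValueError as exc:
                    raise GenotypeParseError(
                        f"{path} line {lineno}: non-integer allele {cell!r}"
                    ) from exc
    return GenotypeTable(individuals, populations, loci, _normalize_missing(alleles))


def _write_genalex(table: GenotypeTable, path: Path, missing_code: int = 0) -> None:
    pops = table.population_ids
    sizes = [table.populations.count(p) for p in pops]
    out = table.alleles.copy()
    out[out == MISSING] = missing_code
    with open(path, "w", newline="") as fh:
        fh.write(",".join(map(str, [table.n_loci, table.n_individuals, len(pops)] + sizes)) + "\n")
        fh.write("genotypes" + "," * (2 + 2 * table.n_loci - 1) + "\n")
        cells = ["Ind", "Pop"]
        for locus in table.loci:
            cells += [locus, ""]
        fh.write(",".join(cells) + "\n")
        for i in range(table.n_individuals):
            row = [table.individuals[i], table.populations[i]]
            for j in range(table.n_loci):
                row += [str(out[i, j, 0]), str(out[i, j, 1])]
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------

def _read_structure(path: Path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # optional locus-name header: genotype rows carry two extra (label, pop)
    # columns, so a header row is two tokens shorter than the row below it
    if len(lines) > 1 and len(lines[0]) == len(lines[1]) - 2:
        loci = list(lines[0])
        body = lines[1:]
    else:
        loci = [f"L{j + 1}" for j in range(len(lines[0]) - 2)]
        body = lines
    if len(body) % 2 != 0:
        raise GenotypeParseError(f"{path}: odd number of genotype rows ({len(body)})")
    n_loci = len(loci)
    n_ind = len(body) // 2
    individuals, populations = [], []
    alleles = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n_ind):
        for k in range(2):
            row = body[2 * i + k]
            lineno = 2 * i + k + 2
            if len(row) != 2 + n_loci:
                raise GenotypeParseError(
                    f"{path} line {lineno}: {len(row)} fields, expected {2 + n_loci}"
                )
            if k == 0:
                individuals.append(row[0])
                populations.append(row[1])
            elif row[0] != individuals[-1]:
                raise GenotypeParseError(
                    f"{path} line {lineno}: row pair label mismatch "
                    f"({row[0]!r} vs {individuals[-1]!r})"
                )
            try:
                alleles[i, :, k] = [int(t) for t in row[2:]]
            except ValueError as exc:
                raise GenotypeParseError(f"{path} line {lineno}: non-integer allele") from exc
    return GenotypeTable(individuals, populations, loci, _normalize_missing(alleles))


def _write_structure(table: GenotypeTable, path: Path, missing_code: int = -9) -> None:
    out = table.alleles.copy()
    out[out == MISSING] = missing_code
    with open(path, "w") as fh:
        fh.write(" ".join(table.loci) + "\n")
        for i in range(table.n_individuals):
            for k in range(2):
                row = [table.individuals[i], table.populations[i]]
                row += [str(out[i, j, k]) for j in range(table.n_loci)]
                fh.write(" ".join(row) + "\n")


_FORMATS = {"genalex-csv": (_read_genalex, _write_genalex),
            "structure-two-row": (_read_structure, _write_structure)}


def read_genotypes(path: str | Path, format: str = "genalex-csv") -> GenotypeTable:
    """Read a genotype file in the declared dialect.

    Allele codes 0 and -9 are both normalized to the internal missing
    sentinel on input.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown genotype format {format!r}; use one of {sorted(_FORMATS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _FORMATS[format][0](path)


def write_genotypes(table: GenotypeTable, path: str | Path, format: str = "genalex-csv") -> None:
    """Write a :class:`GenotypeTable` in the requested dialect."""
    if format not in _FORMATS:
        raise ValueError(f"unknown genotype format {format!r}; use one of {sorted(_FORMATS)}")
    _FORMATS[format][1](table, Path(path))


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

#: Raw measurement columns understood by :func:`derive_traits`.
RAW_TRAIT_COLUMNS = (
    "hs_start", "hs_end",          # height x stem-count product, start/end
    "agbm", "bgbm",                # above-/belowground dry mass (g)
    "dry_mass", "fresh_mass",      # leaf dry and fresh mass (g)
    "ag_c", "ag_n_pct",            # aboveground C and N concentration (%)
    "bg_c", "bg_n_pct",            # belowground C and N concentration (%)
    "root_before_1", "root_after_1",
    "root_before_2", "root_after_2",
    "root_before_3", "root_after_3",
)

DERIVED_TRAIT_COLUMNS = ("rgr", "ldmc", "root_shoot", "ag_cn", "bg_cn", "ag_n", "por")


def _safe_ratio(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
    den = den.astype(float)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{name}: {int(bad.sum())} zero denominator(s) set to missing")
    out = num.astype(float) / den.where(~bad)
    return out


def derive_traits(raw: pd.DataFrame, k_specific: float = 1.0) -> pd.DataFrame:
    """Compute derived quantitative traits from raw common-garden measurements.

    Derivations (each only where its raw columns are present):

    * ``rgr``        relative growth rate, ((H.S)_end - (H.S)_start) / (H.S)_start
    * ``ldmc``       leaf dry-matter content, dry / fresh mass
    * ``root_shoot`` BGBM / AGBM
    * ``ag_cn``, ``bg_cn``  tissue C% / N%
    * ``ag_n``       total aboveground N, (N% / 100) * AGBM (g)
    * ``por``        root porosity: mean over three root segments of
      ((w_after - w_before) / w_after) * ``k_specific``, where ``k_specific``
      is the species-specific root weight factor (default 1.0; the literature
      value for the study species is not published as a number).

    Zero denominators yield missing values with a warning, never an exception.
    Re-deriving an already-derived table reproduces identical values.
    """
    df = raw.copy()
    cols = set(df.columns)
    if {"hs_start", "hs_end"} <= cols:
        df["rgr"] = _safe_ratio(df["hs_end"] - df["hs_start"], df["hs_start"], "rgr")
    if {"dry_mass", "fresh_mass"} <= cols:
        df["ldmc"] = _safe_ratio(df["dry_mass"], df["fresh_mass"], "ldmc")
    if {"bgbm", "agbm"} <= cols:
        df["root_shoot"] = _safe_ratio(df["bgbm"], df["agbm"], "root_shoot")
    if {"ag_c", "ag_n_pct"} <= cols:
        df["ag_cn"] = _safe_ratio(df["ag_c"], df["ag_n_pct"], "ag_cn")
    if {"bg_c", "bg_n_pct"} <= cols:
        df["bg_cn"] = _safe_ratio(df["bg_c"], df["bg_n_pct"], "bg_cn")
    if {"ag_n_pct", "agbm"} <= cols:
        df["ag_n"] = df["ag_n_pct"].astype(float) / 100.0 * df["agbm"].astype(float)
    seg_cols = [(f"root_before_{s}", f"root_after_{s}") for s in (1, 2, 3)]
    if all(b in cols and a in cols for b, a in seg_cols):
        segs = [
            _safe_ratio(df[a] - df[b], df[a], f"por segment {i + 1}") * k_specific
            for i, (b, a) in enumerate(seg_cols)
        ]
        df["por"] = pd.concat(segs, axis=1).mean(axis=1)
    return df


def validate_trait_table(df: pd.DataFrame) -> None:
    """Check the structural invariants of a trait table.

    Seed families must be nested within populations and treatments must be
    one of T0/T70/T150.  Raises ``ValueError`` on violation.
    """
    required = {"individual_id", "population_id", "seed_family_id", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    bad_t = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad_t:
        raise ValueError(f"unknown treatment levels: {sorted(bad_t)}")
    fam_pops = df.groupby("seed_family_id")["population_id"].nunique()
    crossed = fam_pops[fam_pops > 1]
    if len(crossed):
        raise ValueError(
            f"seed families present in more than one population: {list(crossed.index)}"
        )


def read_trait_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a trait table from CSV or an XLSX sheet shaped like the deposited
    individual-level dataset (one row per individual x treatment)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, **kwargs)
    else:
        df = pd.read_csv(path, **kwargs)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# Geography and soil
# ---------------------------------------------------------------------------

def seed_volume(length_mm: float, width_mm: float) -> float:
    """Seed volume in mm^3 assuming a prolate spheroid.

    The long axis is the seed length; the width serves as both minor axes:
    V = (4/3) pi (L/2) (W/2)^2.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(length_mm <= 0) or np.any(width_mm <= 0):
        raise ValueError("seed length and width must be positive")
    vol = (4.0 / 3.0) * np.pi * (length_mm / 2.0) * (width_mm / 2.0) ** 2
    return float(vol) if vol.ndim == 0 else vol


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius EARTH_RADIUS_KM."""
    lat1, lon1, lat2, lon2 = map(np.radians, map(np.asarray, (lat1, lon1, lat2, lon2)))
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geodesic_distance_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Population x population great-circle distance matrix (km).

    ``meta`` needs ``population_id``, ``latitude``, ``longitude`` columns
    (decimal degrees, WGS84 treated as spherical).  Populations with missing
    coordinates are excluded with a warning.
    """
    df = meta[["population_id", "latitude", "longitude"]].copy()
    bad = df[["latitude", "longitude"]].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding populations with missing coordinates: "
            f"{sorted(df.loc[bad, 'population_id'])}"
        )
        df = df[~bad]
    if ((df["latitude"].abs() > 90) | (df["longitude"].abs() > 180)).any():
        raise ValueError("coordinates outside valid decimal-degree ranges")
    pops = df["population_id"].tolist()
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def aggregate_soil(
    points: pd.DataFrame,
    populations: pd.DataFrame,
    radius_km: float = DEFAULT_SOIL_RADIUS_KM,
) -> pd.DataFrame:
    """Average soil point records within ``radius_km`` of each population.

    ``points`` carries ``latitude``, ``longitude`` and soil-variable columns;
    ``populations`` carries ``population_id``, ``latitude``, ``longitude``.
    The radius test is a closed ball (a point at exactly ``radius_km``
    contributes).  Returns one row per population with the arithmetic mean of
    each soil variable and an ``n_points`` count; populations with no points
    in range get missing soil values and a warning.
    """
    soil_vars = [c for c in points.columns if c not in ("latitude", "longitude")]
    rows = []
    for _, pop in populations.iterrows():
        d = haversine_km(
            pop["latitude"], pop["longitude"],
            points["latitude"].to_numpy(), points["longitude"].to_numpy(),
        )
        inside = d <= radius_km + 1e-9  # closed ball, guard fp round-off
        n = int(inside.sum())
        row = {"population_id": pop["population_id"], "n_points": n}
        if n == 0:
            warnings.warn(
                f"population {pop['population_id']}: no soil points within "
                f"{radius_km} km"
            )
            row.update({v: np.nan for v in soil_vars})
        else:
            sub = points.loc[inside, soil_vars]
            row.update(sub.mean().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
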