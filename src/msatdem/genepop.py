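"""Microsatellite genotype data model and GenePop I/O.

A :class:`Dataset` holds an individuals x loci matrix of integer allele
calls together with population, sex and locus-linkage metadata.  Allele
states are raw integers (fragment size or repeat count); most statistics
treat them as categorical labels, while allele-size based statistics use
the integer value directly.

Dialect notes for the GenePop reader/writer:

* 3-digit allele codes, two per genotype (6 characters), missing = ``000``;
* populations separated by lines reading ``Pop`` (case-insensitive);
* a female's genotype at a Z-linked locus written ``xxx000`` is a
  *hemizygous* call with allele ``xxx`` (birds are ZW female / ZZ male),
  not a half-missing diploid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMAL = "autosomal"
Z_LINKED = "z_linked"

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEXES = {MALE, FEMALE, UNKNOWN}


class GenepopParseError(ValueError):
    """Malformed GenePop input (message names the offending line)."""


class DatasetError(ValueError):
    """Inconsistent dataset contents or metadata."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus."""

    name: str
    inheritance: str = AUTOSOMAL
    linkage_group: str | None = None
    map_position: float | None = None  # centimorgans
    motif_step: int = 1

    def __post_init__(self) -> None:
        if self.inheritance not in (AUTOSOMAL, Z_LINKED):
            raise DatasetError(f"unknown inheritance {self.inheritance!r} for locus {self.name}")
        if self.map_position is not None and self.map_position < 0:
            raise DatasetError(f"negative map position for locus {self.name}")


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    sex: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise DatasetError(f"unknown sex {self.sex!r} for individual {self.id}")


class Dataset:
    """Diploid/hemizygous microsatellite genotypes with metadata.

    Parameters
    ----------
    loci
        Ordered locus definitions.
    individuals
        Ordered individuals; population order is first-appearance order.
    alleles
        ``(n_individuals, n_loci, 2)`` integer array.  ``0`` encodes an
        empty slot: ``(0, 0)`` is missing, ``(a, 0)`` with ``a > 0`` is a
        hemizygous call (legal only for females at Z-linked loci), and
        ``(a, b)`` with both positive is a diploid call.
    """

    def __init__(
        self,
        loci: Sequence[LocusDef],
        individuals: Sequence[Individual],
        alleles: np.ndarray,
    ) -> None:
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.alleles = np.asarray(alleles, dtype=np.int32)
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        n, l = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, l, 2):
            raise DatasetError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{n} individuals x {l} loci"
            )
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise DatasetError("duplicate locus names")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate individual ids")
        if (self.alleles < 0).any():
            raise DatasetError("negative allele state")
        a1, a2 = self.alleles[..., 0], self.alleles[..., 1]
        hemi = (a1 > 0) & (a2 == 0)
        if ((a1 == 0) & (a2 > 0)).any():
            raise DatasetError("allele in second slot of an otherwise empty call")
        z_cols = np.array([loc.inheritance == Z_LINKED for loc in self.loci], bool)
        female = np.array([ind.sex == FEMALE for ind in self.individuals], bool)
        bad_hemi = hemi & ~(female[:, None] & z_cols[None, :])
        if bad_hemi.any():
            i, j = np.argwhere(bad_hemi)[0]
            raise DatasetError(
                f"hemizygous call outside female x Z-linked: individual "
                f"{self.individuals[i].id}, locus {self.loci[j].name}"
            )
        diploid_femZ = (a1 > 0) & (a2 > 0) & female[:, None] & z_cols[None, :]
        if diploid_femZ.any():
            i, j = np.argwhere(diploid_femZ)[0]
            raise DatasetError(
                f"diploid Z-linked call for female {self.individuals[i].id} "
                f"at locus {self.loci[j].name}"
            )

    # -- basic accessors -----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def locus_index(self, name: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(name)

    def population_mask(self, population: str) -> np.ndarray:
        return np.array([ind.population == population for ind in self.individuals], bool)

    def sex_array(self) -> np.ndarray:
        return np.array([ind.sex for ind in self.individuals])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_ind, n_loci): True where the call is missing."""
        return (self.alleles[..., 0] == 0) & (self.alleles[..., 1] == 0)

    def typed_copies(self, i: int, j: int) -> list[int]:
        """Allele copies of individual *i* at locus *j* (0, 1 or 2 values)."""
        a, b = self.alleles[i, j]
        return [int(x) for x in (a, b) if x > 0]

    def gene_copies(self, population: str, j: int) -> np.ndarray:
        """All typed gene copies for one population at locus *j*.

        Hemizygous females contribute a single copy at Z-linked loci.
        """
        mask = self.population_mask(population)
        block = self.alleles[mask, j, :]
        return block[block > 0].astype(np.int64)

    def subset_loci(self, keep: Sequence[int]) -> "Dataset":
        keep = list(keep)
        return Dataset(
            [self.loci[j] for j in keep], self.individuals, self.alleles[:, keep, :]
        )

    def copy(self) -> "Dataset":
        return Dataset(list(self.loci), list(self.individuals), self.alleles.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.alleles, other.alleles)
        )

    def __repr__(self) -> str:
        return (
            f"<Dataset {self.n_individuals} individuals x {self.n_loci} loci, "
            f"{len(self.populations)} populations>"
        )


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Tab-separated individual table with header ``id  population  sex``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "sex"}
    if not required.issubset(df.columns):
        raise DatasetError(f"metadata must have columns {sorted(required)}")
    return df


def read_locus_table(path: str | Path) -> list[LocusDef]:
    """Tab-separated locus table: ``locus  linkage_group  position_cM  inheritance``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus", "linkage_group", "position_cM", "inheritance"}
    if not required.issubset(df.columns):
        raise DatasetError(f"locus table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        lg = row["linkage_group"]
        lg = None if (pd.isna(lg) or lg in ("", "NA", "none")) else str(lg)
        pos = row["position_cM"]
        pos = None if (pd.isna(pos) or pos in ("", "NA", "none")) else float(pos)
        out.append(
            LocusDef(
                name=str(row["locus"]),
                inheritance=str(row["inheritance"]),
                linkage_group=lg,
                map_position=pos,
            )
        )
    return out


def write_locus_table(loci: Sequence[LocusDef], path: str | Path) -> None:
    rows = [
        {
            "locus": loc.name,
            "linkage_group": "" if loc.linkage_group is None else loc.linkage_group,
            "position_cM": "" if loc.map_position is None else loc.map_position,
            "inheritance": loc.inheritance,
        }
        for loc in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metadata(individuals: Sequence[Individual], path: str | Path) -> None:
    rows = [{"id": i.id, "population": i.population, "sex": i.sex} for i in individuals]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenePop reader / writer
# ---------------------------------------------------------------------------

def read_genepop(
    path: str | Path,
    metadata: str | Path | pd.DataFrame,
    loci: Sequence[LocusDef] | str | Path | None = None,
) -> Dataset:
    """Parse a GenePop file plus metadata into a validated :class:`Dataset`.

    ``loci`` may be a locus-definition table (path or list); when omitted all
    loci are treated as autosomal with unknown linkage.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    meta_map = {
        str(r["id"]): (str(r["population"]), str(r["sex"])) for _, r in meta.iterrows()
    }
    if isinstance(loci, (str, Path)):
        loci = read_locus_table(loci)

    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty GenePop file")
    # line 0: title.  Locus names follow, either one per line or one
    # comma-separated line, until the first "Pop".
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' line found")

    if loci is None:
        locus_defs = [LocusDef(name) for name in locus_names]
    else:
        by_name = {loc.name: loc for loc in loci}
        missing = [n for n in locus_names if n not in by_name]
        if missing:
            raise DatasetError(f"loci absent from locus table: {missing}")
        locus_defs = [by_name[n] for n in locus_names]
    n_loci = len(locus_defs)
    z_col = [loc.inheritance == Z_LINKED for loc in locus_defs]

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        text = raw.strip()
        if not text:
            continue
        if text.lower() == "pop":
            continue
        if "," not in text:
            raise GenepopParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        ident, geno_part = text.split(",", 1)
        ident = ident.strip()
        if ident not in meta_map:
            raise DatasetError(f"individual {ident!r} absent from metadata")
        population, sex = meta_map[ident]
        codes = geno_part.split()
        if len(codes) != n_loci:
            raise GenepopParseError(
                f"line {lineno + 1}: {len(codes)} genotypes for {n_loci} loci"
            )
        row = np.zeros((n_loci, 2), np.int32)
        for j, code in enumerate(codes):
            if len(code) != 6 or not code.isdigit():
                raise GenepopParseError(
                    f"line {lineno + 1}: malformed allele code {code!r} at locus "
                    f"{locus_defs[j].name}"
                )
            a, b = int(code[:3]), int(code[3:])
            if a == 0 and b > 0:
                # normalise "000xxx" to the hemizygous/diploid convention
                a, b = b, 0
            if a > 0 and b == 0 and not (sex == FEMALE and z_col[j]):
                raise GenepopParseError(
                    f"line {lineno + 1}: half-missing genotype {code!r} for "
                    f"non-(female,Z) call at locus {locus_defs[j].name}"
                )
            row[j] = (a, b)
        individuals.append(Individual(ident, population, sex))
        rows.append(row)

    if not individuals:
        raise GenepopParseError("GenePop file contains no individuals")
    return Dataset(locus_defs, individuals, np.stack(rows))


def write_genepop(dataset: Dataset, path: str | Path, title: str = "msatdem export") -> None:
    """Write the GenePop dialect documented in this module.

    ``read_genepop(write_genepop(d))`` reproduces ``d`` exactly.
    """
    if not dataset.individuals:
        raise DatasetError("cannot write a dataset with no individuals")
    if dataset.alleles.max(initial=0) > 999:
        raise DatasetError("allele state > 999 cannot be encoded in 3 digits")
    buf = io.StringIO()
    buf.write(title + "\n")
    for loc in dataset.loci:
        buf.write(loc.name + "\n")
    current_pop = None
    for i, ind in enumerate(dataset.individuals):
        if ind.population != current_pop:
            buf.write("Pop\n")
            current_pop = ind.population
        codes = [
            f"{int(a):03d}{int(b):03d}" for a, b in dataset.alleles[i]
        ]
        buf.write(f"{ind.id} , " + " ".join(codes) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# locus filters
# ---------------------------------------------------------------------------

@dataclass
class DropReport:
    """Which loci were removed and the populations/groups driving removal."""

    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def removed_loci(self) -> list[str]:
        return list(self.removed)


def drop_failed_loci(
    dataset: Dataset, groups: Mapping[str, str] | None = None
) -> tuple[Dataset, DropReport]:
    """Remove loci that failed to amplify (100% missing) in some population.

    ``groups`` optionally maps population -> group label; missingness is
    then assessed per group.  Loci with *any* fully-missing population (or
    group) are removed — the rule is 100% missing only, a 95% missing cell
    is retained.
    """
    pops = dataset.populations
    if groups is None:
        groups = {p: p for p in pops}
    group_labels: dict[str, list[str]] = {}
    for p in pops:
        group_labels.setdefault(groups.get(p, p), []).append(p)

    missing = dataset.missing_mask()
    report = DropReport()
    keep: list[int] = []
    for j, loc in enumerate(dataset.loci):
        drivers = []
        for g, members in group_labels.items():
            mask = np.zeros(dataset.n_individuals, bool)
            for p in members:
                mask |= dataset.population_mask(p)
            if mask.any() and missing[mask, j].all():
                drivers.append(g)
        if drivers:
            report.removed[loc.name] = drivers
        else:
            keep.append(j)
    return dataset.subset_loci(keep), report


def select_spaced_loci(dataset: Dataset, min_distance: float) -> Dataset:
    """Greedy map-distance thinning: per linkage group, scan in map order and
    keep a locus only if at least ``min_distance`` cM from the last kept one.

    Loci on unique linkage groups (or with no group) are always kept.
    Deterministic given input order; ties in map position keep input order.
    """
    by_group: dict[str, list[int]] = {}
    singletons: list[int] = []
    for j, loc in enumerate(dataset.loci):
        if loc.linkage_group is None:
            singletons.append(j)
        else:
            by_group.setdefault(loc.linkage_group, []).append(j)

    keep = set(singletons)
    for group, idx in by_group.items():
        if len(idx) == 1:
            keep.add(idx[0])
            continue
        for j in idx:
            if dataset.loci[j].map_position is None:
                raise DatasetError(
                    f"locus {dataset.loci[j].name} on multi-locus group {group} "
                    "lacks a map position"
                )
        order = sorted(idx, key=lambda j: (dataset.loci[j].map_position, idx.index(j)))
        last = None
        for j in order:
            pos = dataset.loci[j].map_position
            if last is None or pos - last >= min_distance:
                keep.add(j)
                last = pos
    return dataset.subset_loci([j for j in range(dataset.n_loci) if j in keep])
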