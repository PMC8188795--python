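"""Genotype data model, validation and file I/O.

Diploid co-dominant SSR genotypes are held as an (individuals x loci x 2)
integer array of dense per-locus allele codes, with ``MISSING`` (-1) marking
missing calls.  Two text layouts are supported: a delimited wide table
(GenAlEx-style: id, population, then two columns per locus) and the
STRUCTURE two-rows-per-individual format.  Original allele labels (fragment
sizes or arbitrary codes) are retained in a per-locus lookup.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
#: sentinel written to / expected in files for a missing allele
FILE_MISSING = "0"

SPECIES_CODES = ("A", "V", "F", "B")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the expected layout."""


class MetadataError(ValueError):
    """Raised when sample metadata is inconsistent with the genotype matrix."""


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a global seed.

    String keys are hashed (CRC32) so that every stage of the pipeline gets
    its own stream: toggling one stage never shifts another's draws.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid allele-code matrix.

    ``calls[i, l]`` is a pair of dense integer allele codes (sorted; order
    carries no meaning) or ``(MISSING, MISSING)``.  ``allele_labels[locus]``
    maps dense code -> original label.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray  # (n, L, 2) int32
    allele_labels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    def n_alleles(self, locus_index: int) -> int:
        c = self.calls[:, locus_index, :]
        c = c[c != MISSING]
        return 0 if c.size == 0 else int(c.max()) + 1

    def subset(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            [self.individuals[i] for i in indices],
            list(self.loci),
            self.calls[indices].copy(),
            self.allele_labels,
        )

    def labelled_calls(self) -> list[list[tuple]]:
        """Calls as sorted original-label pairs (None = missing); the
        relabeling-invariant view used for equality."""
        out = []
        for i in range(self.n_individuals):
            row = []
            for l, locus in enumerate(self.loci):
                a, b = self.calls[i, l]
                if a == MISSING:
                    row.append((None, None))
                else:
                    lk = self.allele_labels.get(locus)
                    pair = (lk[a], lk[b]) if lk else (str(a), str(b))
                    row.append(tuple(sorted(pair)))
            out.append(row)
        return out

    def __eq__(self, other) -> bool:
        """Equality up to dense-code relabeling: identical individuals,
        loci, missing pattern and original-label genotypes."""
        if not (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.loci == other.loci
        ):
            return False
        if np.array_equal(self.calls, other.calls) and not (
            self.allele_labels or other.allele_labels
        ):
            return True
        return self.labelled_calls() == other.labelled_calls()


@dataclass
class SampleMetadata:
    """Per-individual population / species / site labels.

    Population codes follow the SITE-SPECIES convention (e.g. ``BY-A`` =
    site BY, species A); a custom population->(species, site) mapping may be
    supplied instead.
    """

    table: pd.DataFrame  # index: individual; columns: population, species, site

    @classmethod
    def from_populations(
        cls,
        individuals: list[str],
        populations: list[str],
        pop_map: dict[str, tuple[str, str]] | None = None,
    ) -> "SampleMetadata":
        species, sites = [], []
        for pop in populations:
            if pop_map is not None:
                if pop not in pop_map:
                    raise MetadataError(f"unknown population code {pop!r}")
                sp, site = pop_map[pop]
            elif "-" in pop:
                site, sp = pop.rsplit("-", 1)
            else:
                sp, site = pop, pop
            species.append(sp)
            sites.append(site)
        if len(set(individuals)) != len(individuals):
            dup = pd.Series(individuals).value_counts()
            raise MetadataError(
                f"duplicate individual id(s): {list(dup.index[dup > 1])}"
            )
        tab = pd.DataFrame(
            {"population": populations, "species": species, "site": sites},
            index=pd.Index(individuals, name="individual"),
        )
        # a population code must map to exactly one species and one site
        chk = tab.groupby("population")[["species", "site"]].nunique()
        if (chk > 1).any().any():
            raise MetadataError("population code maps to >1 species or site")
        return cls(tab)

    @property
    def populations(self) -> pd.Series:
        return self.table["population"]

    @property
    def species(self) -> pd.Series:
        return self.table["species"]

    @property
    def sites(self) -> pd.Series:
        return self.table["site"]

    def groups(self, by: str = "population") -> pd.Series:
        if by not in ("population", "species", "site"):
            raise MetadataError(f"unknown grouping level {by!r}")
        return self.table[by]

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.table.equals(other.table)


def validate_matrix(matrix: GenotypeMatrix) -> None:
    """Check structural invariants; raise GenotypeFormatError on violation."""
    n, L = matrix.n_individuals, matrix.n_loci
    if n == 0:
        raise GenotypeFormatError("matrix has no individuals")
    if L == 0:
        raise GenotypeFormatError("matrix has no loci")
    if matrix.calls.shape != (n, L, 2):
        raise GenotypeFormatError(f"calls shape {matrix.calls.shape} != ({n},{L},2)")
    half = (matrix.calls == MISSING).sum(axis=2) == 1
    if half.any():
        raise GenotypeFormatError("half-missing call present after normalization")
    for l, name in enumerate(matrix.loci):
        if (matrix.calls[:, l, 0] == MISSING).all():
            raise GenotypeFormatError(f"locus {name!r} has no non-missing calls")


def _normalize_calls(raw: np.ndarray) -> np.ndarray:
    """Sort allele pairs; treat half-missing calls as fully missing."""
    calls = np.sort(raw, axis=2)  # MISSING=-1 sorts first
    half = (calls[:, :, 0] == MISSING) & (calls[:, :, 1] != MISSING)
    calls[half] = MISSING
    return calls


def build_matrix(
    individuals: list[str],
    loci: list[str],
    labels: list[list[tuple[str, str]]],
    missing: str = FILE_MISSING,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from raw per-call label pairs.

    ``labels[i][l]`` is the (a, b) label pair for individual i at locus l.
    Labels are re-encoded to dense integers per locus; lookup retained.
    """
    n, L = len(individuals), len(loci)
    calls = np.full((n, L, 2), MISSING, dtype=np.int32)
    allele_labels: dict[str, list[str]] = {}
    for l, locus in enumerate(loci):
        lookup: dict[str, int] = {}
        order: list[str] = []
        for i in range(n):
            a, b = labels[i][l]
            for j, lab in enumerate((a, b)):
                if lab == missing or lab == "":
                    continue
                if lab not in lookup:
                    lookup[lab] = len(order)
                    order.append(lab)
                calls[i, l, j] = lookup[lab]
        allele_labels[locus] = order
    calls = _normalize_calls(calls)
    m = GenotypeMatrix(list(individuals), list(loci), calls, allele_labels)
    validate_matrix(m)
    return m


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_delim(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_genotypes(
    path,
    format_tag: str = "delimited-wide",
    missing: str = FILE_MISSING,
    pop_map: dict[str, tuple[str, str]] | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Read a genotype file; returns validated matrix plus metadata.

    format_tag: ``delimited-wide`` (id, pop, then two columns per locus with
    the locus name heading both) or ``structure-two-row`` (header of locus
    names; then two rows per individual, each id, pop, one allele per locus).
    """
    if format_tag == "delimited-wide":
        return _read_wide(path, missing, pop_map)
    if format_tag == "structure-two-row":
        return _read_structure(path, missing, pop_map)
    raise GenotypeFormatError(f"unknown format_tag {format_tag!r}")


def _read_rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise GenotypeFormatError(f"{path}: empty file")
        delim = _sniff_delim(first)
        fh.seek(0)
        return [row for row in csv.reader(fh, delimiter=delim) if any(f.strip() for f in row)]


def _read_wide(path, missing, pop_map):
    rows = _read_rows(path)
    header = [f.strip() for f in rows[0]]
    locus_cols = header[2:]
    if len(locus_cols) == 0 or len(locus_cols) % 2 != 0:
        raise GenotypeFormatError(
            f"{path}: expected an even number of locus columns, got {len(locus_cols)}"
        )
    loci = []
    for j in range(0, len(locus_cols), 2):
        a, b = locus_cols[j], locus_cols[j + 1]
        if b not in (a, ""):
            raise GenotypeFormatError(
                f"{path}: locus header pair mismatch at columns {j + 2},{j + 3}: {a!r}/{b!r}"
            )
        loci.append(a)
    individuals, pops, labels = [], [], []
    for r, row in enumerate(rows[1:], start=2):
        row = [f.strip() for f in row]
        if len(row) != 2 + 2 * len(loci):
            raise GenotypeFormatError(
                f"{path}: row {r} ({row[0]!r}) has {len(row) - 2} allele fields; "
                f"expected {2 * len(loci)} (odd allele count or truncated row)"
            )
        individuals.append(row[0])
        pops.append(row[1])
        labels.append([(row[2 + 2 * j], row[3 + 2 * j]) for j in range(len(loci))])
    matrix = build_matrix(individuals, loci, labels, missing)
    meta = SampleMetadata.from_populations(individuals, pops, pop_map)
    return matrix, meta


def _read_structure(path, missing, pop_map):
    rows = _read_rows(path)
    header = [f.strip() for f in rows[0]]
    body = rows[1:]
    if not body:
        raise GenotypeFormatError(f"{path}: no data rows")
    L = len(body[0]) - 2
    if len(header) == L:  # header carries just the locus names
        loci = header
    else:
        raise GenotypeFormatError(
            f"{path}: header has {len(header)} locus names but rows imply {L}"
        )
    if len(body) % 2 != 0:
        raise GenotypeFormatError(f"{path}: odd number of data rows ({len(body)})")
    individuals, pops, labels = [], [], []
    for k in range(0, len(body), 2):
        r1 = [f.strip() for f in body[k]]
        r2 = [f.strip() for f in body[k + 1]]
        if len(r1) != L + 2 or len(r2) != L + 2:
            raise GenotypeFormatError(f"{path}: row length mismatch near row {k + 2}")
        if r1[0] != r2[0]:
            raise GenotypeFormatError(
                f"{path}: consecutive rows for different individuals "
                f"({r1[0]!r} vs {r2[0]!r}) — rows must come in pairs"
            )
        individuals.append(r1[0])
        pops.append(r1[1])
        labels.append([(r1[2 + j], r2[2 + j]) for j in range(L)])
    matrix = build_matrix(individuals, loci, labels, missing)
    meta = SampleMetadata.from_populations(individuals, pops, pop_map)
    return matrix, meta


def write_genotypes(
    matrix: GenotypeMatrix,
    metadata: SampleMetadata,
    path,
    format_tag: str = "delimited-wide",
    missing: str = FILE_MISSING,
    delimiter: str = ",",
) -> None:
    """Write a genotype file readable back by :func:`read_genotypes`."""
    validate_matrix(matrix)
    pops = metadata.populations
    labels = {
        locus: matrix.allele_labels.get(locus) or None for locus in matrix.loci
    }

    def lab(l, code):
        if code == MISSING:
            return missing
        locus = matrix.loci[l]
        lk = labels[locus]
        return lk[code] if lk else str(code + 1)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        if format_tag == "delimited-wide":
            header = ["individual", "population"]
            for locus in matrix.loci:
                header += [locus, locus]
            w.writerow(header)
            for i, ind in enumerate(matrix.individuals):
                row = [ind, pops.loc[ind]]
                for l in range(matrix.n_loci):
                    row += [lab(l, matrix.calls[i, l, 0]), lab(l, matrix.calls[i, l, 1])]
                w.writerow(row)
        elif format_tag == "structure-two-row":
            w.writerow(list(matrix.loci))
            for i, ind in enumerate(matrix.individuals):
                for j in (0, 1):
                    w.writerow(
                        [ind, pops.loc[ind]]
                        + [lab(l, matrix.calls[i, l, j]) for l in range(matrix.n_loci)]
                    )
        else:
            raise GenotypeFormatError(f"unknown format_tag {format_tag!r}")


def read_traits(path) -> pd.DataFrame:
    """Read a delimited trait matrix (first column = individual id)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] < 1:
        raise GenotypeFormatError(f"{path}: trait matrix needs >=1 trait column")
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="individual")


# ---------------------------------------------------------------------------
# Allele counting (substrate for all statistics)
# ---------------------------------------------------------------------------

def allele_counts(
    matrix: GenotypeMatrix, grouping: pd.Series
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group allele-copy counts.

    Returns ``{group: (counts, missing)}`` with ``counts[l, a]`` the number
    of copies of allele ``a`` at locus ``l`` and ``missing[l]`` the number of
    missing calls.  Conservation: ``counts.sum(1) + 2*missing == 2*n_group``.
    """
    grouping = grouping.reindex(matrix.individuals)
    if grouping.isna().any():
        raise MetadataError("grouping does not cover every individual")
    A = max(matrix.n_alleles(l) for l in range(matrix.n_loci))
    out = {}
    for g, idx in grouping.groupby(grouping).groups.items():
        rows = np.array([matrix.individuals.index(i) for i in idx])
        if rows.size == 0:
            raise MetadataError(f"group {g!r} has zero individuals")
        calls = matrix.calls[rows]  # (m, L, 2)
        counts = np.zeros((matrix.n_loci, A), dtype=np.int64)
        for l in range(matrix.n_loci):
            c = calls[:, l, :].ravel()
            c = c[c != MISSING]
            if c.size:
                counts[l, : c.max() + 1] = np.bincount(c)
        missing = (calls[:, :, 0] == MISSING).sum(axis=0)
        out[g] = (counts, missing.astype(np.int64))
    return out


def allele_count_table(matrix: GenotypeMatrix, grouping: pd.Series) -> pd.DataFrame:
    """Long-format allele count table (group, locus, allele label, count)."""
    counts = allele_counts(matrix, grouping)
    rows = []
    for g, (cnt, miss) in counts.items():
        for l, locus in enumerate(matrix.loci):
            labels = matrix.allele_labels.get(locus) or [
                str(a + 1) for a in range(matrix.n_alleles(l))
            ]
            for a in range(matrix.n_alleles(l)):
                if cnt[l, a]:
                    rows.append((g, locus, labels[a], int(cnt[l, a])))
            rows.append((g, locus, "<missing>", int(miss[l])))
    return pd.DataFrame(rows, columns=["group", "locus", "allele", "count"])
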