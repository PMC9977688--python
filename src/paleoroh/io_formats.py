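"""Readers and writers for the text formats of the 1240k ecosystem.

This module houses the shared coordinate model (:class:`SNPSite`,
:class:`GenomeMap`), the in-memory genotype container
(:class:`GenotypeTable`), the per-library read-count container
(:class:`LibraryPileup`) and I/O for:

* EIGENSTRAT geno/snp/ind trios (text dialect, one packed ASCII-digit row
  per SNP);
* per-site read counts, either as samtools-mpileup text or as a
  pre-tabulated 6-column TSV;
* genetic maps as 3-column TSV (chrom, bp, cM).

Coordinates are 1-based inclusive throughout.  Pseudo-haploid genotypes are
stored internally as alt-allele indicators {0, 1} with ``-1`` for missing,
regardless of the on-disk dosage encoding; pseudo-diploid genotypes store
alt-allele dosages {0, 1, 2} with ``-1`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "FormatError",
    "SNPSite",
    "GenomeMap",
    "GenotypeTable",
    "LibraryProtocol",
    "LibraryPileup",
    "EigenstratData",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_pileup_counts",
    "DEFAULT_AUTOSOME_LENGTHS_CM",
]

MISSING = -1

#: Sex-averaged genetic lengths (cM) of the 22 human autosomes, rescaled to
#: a 35.4 Morgan total — the default genome used by the Ne model when no
#: genetic map is supplied.
_RAW_AUTOSOME_CM = np.array(
    [286.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0, 166.0, 181.0,
     158.0, 175.0, 126.0, 120.0, 142.0, 134.0, 129.0, 118.0, 108.0, 108.0,
     62.0, 74.0]
)
DEFAULT_AUTOSOME_LENGTHS_CM = _RAW_AUTOSOME_CM * (3540.0 / _RAW_AUTOSOME_CM.sum())


class FormatError(ValueError):
    """A structural problem in an input file (dimension mismatch, bad digit...)."""


@dataclass(frozen=True)
class SNPSite:
    """One capture-panel site: alleles plus physical and genetic coordinates."""

    chrom: str
    pos_bp: int
    pos_cM: float
    ref_allele: str
    alt_allele: str
    snp_id: str = ""

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.snp_id}")

    @property
    def is_transition(self) -> bool:
        pair = frozenset((self.ref_allele.upper(), self.alt_allele.upper()))
        return pair in (frozenset("CT"), frozenset("GA"))

    @property
    def is_ct(self) -> bool:
        return frozenset((self.ref_allele.upper(), self.alt_allele.upper())) == frozenset("CT")

    @property
    def is_ga(self) -> bool:
        return frozenset((self.ref_allele.upper(), self.alt_allele.upper())) == frozenset("GA")


def validate_site_order(sites: Sequence[SNPSite]) -> None:
    """Raise :class:`FormatError` if pos_cM decreases within a chromosome.

    Sites must already be grouped by chromosome and sorted by pos_bp; a
    genetic-map position that moves backwards is an error, never silently
    reordered.
    """
    prev_chrom, prev_bp, prev_cm = None, -1, -np.inf
    for s in sites:
        if s.chrom == prev_chrom:
            if s.pos_bp < prev_bp:
                raise FormatError(
                    f"sites not sorted by pos_bp on chrom {s.chrom} at {s.snp_id}"
                )
            if s.pos_cM < prev_cm:
                raise FormatError(
                    f"pos_cM decreases on chrom {s.chrom} at {s.snp_id} "
                    f"({s.pos_cM} < {prev_cm})"
                )
        prev_chrom, prev_bp, prev_cm = s.chrom, s.pos_bp, s.pos_cM


class GenomeMap:
    """Per-chromosome monotone bp→cM interpolation tables.

    Parameters
    ----------
    tables
        Mapping ``chrom -> (bp_array, cM_array)`` with both arrays sorted
        ascending and cM non-decreasing.
    """

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in tables.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"map for chrom {chrom} needs >= 2 anchor points")
            if np.any(np.diff(bp) <= 0):
                raise FormatError(f"map bp not strictly increasing on chrom {chrom}")
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"map cM not monotone on chrom {chrom}")
            if cm[-1] - cm[0] <= 0:
                raise FormatError(f"chrom {chrom} has zero genetic length")
            self._tables[chrom] = (bp, cm)

    @property
    def chroms(self) -> list[str]:
        return list(self._tables)

    def cm_at(self, chrom: str, pos_bp: np.ndarray | float) -> np.ndarray | float:
        """Interpolate genetic position (cM); clamps outside the anchor range."""
        bp, cm = self._tables[chrom]
        return np.interp(pos_bp, bp, cm)

    def chrom_length_morgans(self, chrom: str) -> float:
        bp, cm = self._tables[chrom]
        return float(cm[-1] - cm[0]) / 100.0

    def lengths_morgans(self) -> np.ndarray:
        return np.array([self.chrom_length_morgans(c) for c in self._tables])

    def total_morgans(self) -> float:
        return float(self.lengths_morgans().sum())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeMap":
        """Read a 3-column TSV (chrom, bp, cM); header optional."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise FormatError(f"genetic map {path}: expected 3 columns")
        # drop a header row if the bp column is not numeric
        if not df.iloc[0, 1].lstrip("-").replace(".", "", 1).isdigit():
            df = df.iloc[1:]
        tables = {}
        for chrom, grp in df.groupby(0, sort=False):
            tables[str(chrom)] = (
                grp[1].astype(float).to_numpy(),
                grp[2].astype(float).to_numpy(),
            )
        return cls(tables)

    @classmethod
    def constant_rate(
        cls,
        chrom_extents_bp: dict[str, tuple[int, int]],
        cm_per_mb: float = 1.0,
    ) -> "GenomeMap":
        """Uniform-recombination fallback map (default 1 cM/Mb)."""
        tables = {}
        for chrom, (lo, hi) in chrom_extents_bp.items():
            bp = np.array([float(lo), float(hi)])
            cm = (bp - lo) * cm_per_mb / 1e6
            tables[chrom] = (bp, cm)
        return cls(tables)

    @classmethod
    def default_autosomes(cls) -> "GenomeMap":
        """22 linear autosomal maps with the default cM lengths (35.4 M total)."""
        tables = {}
        for i, length_cm in enumerate(DEFAULT_AUTOSOME_LENGTHS_CM, start=1):
            bp = np.array([1.0, length_cm * 1e6])
            cm = np.array([0.0, length_cm])
            tables[str(i)] = (bp, cm)
        return cls(tables)


class GenotypeTable:
    """Genotype matrix over (individual, site).

    ``ploidy='pseudo_haploid'`` stores alt-allele indicators {0, 1};
    ``ploidy='pseudo_diploid'`` stores alt dosages {0, 1, 2}.  Missing is
    ``-1`` in both.
    """

    PLOIDIES = ("pseudo_haploid", "pseudo_diploid")

    def __init__(self, data: np.ndarray, individuals: Sequence[str], ploidy: str):
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise ValueError("genotype data must be 2-D (individuals x sites)")
        if ploidy not in self.PLOIDIES:
            raise ValueError(f"unknown ploidy {ploidy!r}")
        hi = 1 if ploidy == "pseudo_haploid" else 2
        bad = (data < MISSING) | (data > hi)
        if bad.any():
            raise ValueError(f"genotype values outside {{-1..{hi}}} present")
        if len(individuals) != data.shape[0]:
            raise ValueError("individuals length != number of rows")
        self.data = data
        self.individuals = list(individuals)
        self.ploidy = ploidy
        self._covered: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def covered_counts(self) -> np.ndarray:
        """Number of non-missing sites per individual (cached)."""
        if self._covered is None:
            self._covered = (self.data != MISSING).sum(axis=1)
        return self._covered

    def row(self, individual: str) -> np.ndarray:
        return self.data[self.individuals.index(individual)]


@dataclass(frozen=True)
class LibraryProtocol:
    """Library construction protocol, deciding which reads are call-eligible.

    The four supported combinations are ds_nonUDG, ds_halfUDG, ss_nonUDG and
    ss_halfUDG; double-stranded half-UDG libraries must have 2 bp masked
    from both read ends upstream.
    """

    strand_type: str  # "double" | "single"
    udg: str  # "none" | "half"
    damage_mask_bp: int = 0

    def __post_init__(self):
        if self.strand_type not in ("double", "single"):
            raise ValueError(f"strand_type must be double|single, got {self.strand_type}")
        if self.udg not in ("none", "half"):
            raise ValueError(f"udg must be none|half, got {self.udg}")
        if self.damage_mask_bp < 0:
            raise ValueError("damage_mask_bp must be >= 0")
        if self.name == "ds_halfUDG" and self.damage_mask_bp != 2:
            raise ValueError("ds_halfUDG requires damage_mask_bp == 2")

    @property
    def name(self) -> str:
        return ("ds" if self.strand_type == "double" else "ss") + "_" + (
            "nonUDG" if self.udg == "none" else "halfUDG"
        )

    @classmethod
    def from_name(cls, name: str) -> "LibraryProtocol":
        try:
            st, udg = name.split("_")
        except ValueError:
            raise ValueError(f"unknown protocol {name!r}") from None
        strand = {"ds": "double", "ss": "single"}.get(st)
        u = {"nonUDG": "none", "halfUDG": "half"}.get(udg)
        if strand is None or u is None:
            raise ValueError(f"unknown protocol {name!r}")
        mask = 2 if name == "ds_halfUDG" else 0
        return cls(strand, u, mask)


@dataclass
class LibraryPileup:
    """Per-library stranded ref/alt read counts aligned to a panel site list.

    Attributes are full-length arrays over the panel (zero where the library
    has no reads).  ``meta`` records ingest bookkeeping: retained / dropped /
    off-panel base tallies and the assumed upstream quality threshold.
    """

    library_id: str
    n_ref_fwd: np.ndarray
    n_ref_rev: np.ndarray
    n_alt_fwd: np.ndarray
    n_alt_rev: np.ndarray
    protocol: LibraryProtocol | None = None
    pmd_filtered: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arrs = [self.n_ref_fwd, self.n_ref_rev, self.n_alt_fwd, self.n_alt_rev]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError("count arrays must share one shape")
        for a in arrs:
            if (np.asarray(a) < 0).any():
                raise ValueError("negative read count")

    @property
    def n_sites(self) -> int:
        return self.n_ref_fwd.shape[0]

    @property
    def n_ref(self) -> np.ndarray:
        return self.n_ref_fwd + self.n_ref_rev

    @property
    def n_alt(self) -> np.ndarray:
        return self.n_alt_fwd + self.n_alt_rev

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt


@dataclass
class EigenstratData:
    """Bundle returned by :func:`read_eigenstrat`."""

    table: GenotypeTable
    sites: list[SNPSite]
    individuals: pd.DataFrame  # columns: id, sex, population
    cm_backfilled: bool = False


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    ploidy: str = "auto",
    genome_map: GenomeMap | None = None,
) -> EigenstratData:
    """Read an EIGENSTRAT geno/snp/ind trio.

    The on-disk geno digits are alt-allele dosages with 9 = missing.
    Pseudo-haploid tables (digits restricted to {0, 2, 9}) are converted to
    alt indicators {0, 1, -1}; any het digit 1 forces pseudo-diploid.  The
    .snp genetic-position column is in Morgans and is converted to cM; if it
    is zero everywhere the genetic position is backfilled from
    ``genome_map`` (default: constant 1 cM/Mb) and ``cm_backfilled`` is set.
    """
    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "population"],
        dtype=str,
    )
    snp = pd.read_csv(
        snp_path, sep=r"\s+", header=None,
        names=["snp_id", "chrom", "gpos_m", "pos_bp", "ref", "alt"],
        dtype={"snp_id": str, "chrom": str},
    )
    geno_lines = Path(geno_path).read_text().splitlines()
    if len(geno_lines) != len(snp):
        raise FormatError(
            f"geno has {len(geno_lines)} rows but snp lists {len(snp)} sites"
        )
    n_ind = len(ind)
    rows = np.empty((len(geno_lines), n_ind), dtype=np.int8)
    for i, line in enumerate(geno_lines):
        if len(line) != n_ind:
            raise FormatError(
                f"geno row {i + 1} has {len(line)} characters, expected {n_ind}"
            )
        try:
            rows[i] = [int(ch) for ch in line]
        except ValueError:
            raise FormatError(f"non-numeric genotype character in geno row {i + 1}")
    bad = ~np.isin(rows, (0, 1, 2, 9))
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise FormatError(f"invalid genotype digit in geno row {i + 1}")

    data = rows.T.copy()  # (individual, site), alt dosage
    has_het = bool((data == 1).any())
    if ploidy == "auto":
        ploidy = "pseudo_diploid" if has_het else "pseudo_haploid"
    if ploidy == "pseudo_haploid":
        if has_het:
            raise FormatError("het digit 1 present in a pseudo-haploid geno")
        data = np.where(data == 9, MISSING, data // 2).astype(np.int8)
    else:
        data = np.where(data == 9, MISSING, data).astype(np.int8)

    gpos_cm = snp["gpos_m"].astype(float).to_numpy() * 100.0
    cm_backfilled = False
    if np.allclose(gpos_cm, 0.0):
        cm_backfilled = True
        if genome_map is None:
            extents = {
                str(c): (1, int(g["pos_bp"].max()) + 1)
                for c, g in snp.groupby("chrom", sort=False)
            }
            genome_map = GenomeMap.constant_rate(extents)
        gpos_cm = np.array(
            [genome_map.cm_at(c, p) for c, p in zip(snp["chrom"], snp["pos_bp"])]
        )
        warnings.warn("snp genetic positions all zero; backfilled from genome map")

    sites = [
        SNPSite(str(c), int(p), float(cm), str(r), str(a), str(i))
        for c, p, cm, r, a, i in zip(
            snp["chrom"], snp["pos_bp"], gpos_cm, snp["ref"], snp["alt"],
            snp["snp_id"],
        )
    ]
    validate_site_order(sites)
    table = GenotypeTable(data, ind["id"].tolist(), ploidy)
    return EigenstratData(table, sites, ind, cm_backfilled)


def write_eigenstrat(
    table: GenotypeTable,
    sites: Sequence[SNPSite],
    individuals: pd.DataFrame | Sequence,
    out_prefix: str | Path,
) -> None:
    """Write an EIGENSTRAT trio to ``<out_prefix>.{geno,snp,ind}``.

    Pseudo-haploid alt indicators go to disk as dosages {0, 2}; missing as 9.
    Genetic positions are written in Morgans with 6 decimals.
    """
    out_prefix = Path(out_prefix)
    if len(sites) != table.n_sites:
        raise ValueError("sites length != table.n_sites")
    data = table.data
    if table.ploidy == "pseudo_haploid":
        disk = np.where(data == MISSING, 9, data * 2)
    else:
        disk = np.where(data == MISSING, 9, data)
    disk = disk.T.astype(np.uint8)  # (site, individual)
    digits = np.char.mod("%d", disk)
    with open(out_prefix.with_suffix(".geno"), "w") as fh:
        for row in digits:
            fh.write("".join(row) + "\n")
    with open(out_prefix.with_suffix(".snp"), "w") as fh:
        for s in sites:
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.pos_cM / 100.0:.6f}\t{s.pos_bp}"
                f"\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    if isinstance(individuals, pd.DataFrame):
        rows = individuals[["id", "sex", "population"]].itertuples(index=False)
    else:
        rows = individuals
    with open(out_prefix.with_suffix(".ind"), "w") as fh:
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\n")


# ---------------------------------------------------------------------------
# pileup ingest
# ---------------------------------------------------------------------------

def _parse_mpileup_bases(
    bases: str, ref: str, alt: str, line_no: int
) -> tuple[int, int, int, int, int]:
    """Tally one mpileup base string.

    Returns (n_ref_fwd, n_ref_rev, n_alt_fwd, n_alt_rev, n_dropped).
    Handles ^X read starts, $ ends, indel runs and * deletions; bases that
    are neither the panel ref nor alt (including N) are dropped and tallied.
    """
    nrf = nrr = naf = nar = dropped = 0
    ref_u, alt_u = ref.upper(), alt.upper()
    i, n = 0, len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # mapping-quality char follows
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise FormatError(f"malformed indel in pileup line {line_no}")
            i += int(num)
            continue
        if ch == ".":
            nrf += 1
        elif ch == ",":
            nrr += 1
        elif ch.isalpha():
            up = ch.upper()
            fwd = ch.isupper()
            if up == alt_u:
                naf, nar = (naf + 1, nar) if fwd else (naf, nar + 1)
            elif up == ref_u:
                nrf, nrr = (nrf + 1, nrr) if fwd else (nrf, nrr + 1)
            else:
                dropped += 1
        elif ch in "*<>":
            dropped += 1
        else:
            raise FormatError(f"unexpected pileup character {ch!r} on line {line_no}")
        i += 1
    return nrf, nrr, naf, nar, dropped


def read_pileup_counts(
    path: str | Path,
    panel_sites: Sequence[SNPSite],
    library_id: str | None = None,
    protocol: LibraryProtocol | None = None,
    pmd_filtered: bool = False,
) -> LibraryPileup:
    """Read per-site read counts into a :class:`LibraryPileup`.

    Accepts either samtools-mpileup text (chrom, pos, refbase, depth, bases,
    quals) or a pre-tabulated 6-column TSV (chrom, pos, n_ref_fwd, n_ref_rev,
    n_alt_fwd, n_alt_rev).  Rows at positions not in the panel are skipped
    and counted; triallelic observations are dropped, not recoded.  Base and
    mapping quality >= 30 is assumed applied upstream and recorded in
    ``meta``.
    """
    path = Path(path)
    index = {(s.chrom, s.pos_bp): i for i, s in enumerate(panel_sites)}
    S = len(panel_sites)
    nrf = np.zeros(S, dtype=np.int32)
    nrr = np.zeros(S, dtype=np.int32)
    naf = np.zeros(S, dtype=np.int32)
    nar = np.zeros(S, dtype=np.int32)
    skipped_sites = 0
    offpanel_bases = 0
    dropped_bases = 0

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"pileup line {line_no}: too few columns")
            chrom, pos_s = fields[0], fields[1]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"pileup line {line_no}: bad position {pos_s!r}")
            tabular = len(fields) >= 6 and all(_is_float(f) for f in fields[2:6])
            idx = index.get((chrom, pos))
            if tabular:
                counts = [int(float(f)) for f in fields[2:6]]
                if any(c < 0 for c in counts):
                    raise FormatError(f"pileup line {line_no}: negative count")
                if idx is None:
                    skipped_sites += 1
                    offpanel_bases += sum(counts)
                    continue
                nrf[idx] += counts[0]
                nrr[idx] += counts[1]
                naf[idx] += counts[2]
                nar[idx] += counts[3]
            else:
                if idx is None:
                    skipped_sites += 1
                    try:
                        offpanel_bases += int(fields[3])
                    except (ValueError, IndexError):
                        pass
                    continue
                site = panel_sites[idx]
                a, b, c, d, drop = _parse_mpileup_bases(
                    fields[4], site.ref_allele, site.alt_allele, line_no
                )
                nrf[idx] += a
                nrr[idx] += b
                naf[idx] += c
                nar[idx] += d
                dropped_bases += drop

    return LibraryPileup(
        library_id=library_id or path.stem,
        n_ref_fwd=nrf, n_ref_rev=nrr, n_alt_fwd=naf, n_alt_rev=nar,
        protocol=protocol, pmd_filtered=pmd_filtered,
        meta={
            "skipped_sites": skipped_sites,
            "offpanel_bases": offpanel_bases,
            "dropped_bases": dropped_bases,
            "retained_bases": int(nrf.sum() + nrr.sum() + naf.sum() + nar.sum()),
            "quality_threshold": 30,
        },
    )
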