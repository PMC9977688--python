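"""Protocol-aware genotype calling from read counts, library merging and QC.

Pseudo-haploid calling samples one read per site uniformly among the
protocol-eligible reads; pseudo-diploid calling draws two reads without
replacement.  Eligibility depends on the library protocol:

* ds_halfUDG — all reads at all sites (2 bp end-masking applied upstream);
* ds_nonUDG — transversion sites only (C↔T and G↔A SNPs are uncallable,
  being confounded by deamination damage);
* ss_nonUDG / ss_halfUDG — single-strand rule: forward reads are ignored at
  C/T SNPs and reverse reads at G/A SNPs.

Also here: random-allele merging of per-library calls, the minimum-SNP
individual filter, and coverage-ratio genetic sex assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    MISSING,
    GenotypeTable,
    LibraryPileup,
    LibraryProtocol,
    SNPSite,
)

__all__ = [
    "LibraryProtocol",
    "LibraryPileup",
    "SexAssignment",
    "eligible_counts",
    "call_pseudohaploid",
    "call_pseudodiploid",
    "merge_libraries",
    "filter_min_snps",
    "assign_sex",
]


def eligible_counts(
    pileup: LibraryPileup, sites: Sequence[SNPSite]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n_ref, n_alt) after applying the protocol eligibility rules.

    Filters only remove reads; they never flip alleles.
    """
    proto = pileup.protocol
    if proto is None:
        raise ValueError(f"library {pileup.library_id}: no protocol declared")
    name = proto.name
    if name not in ("ds_nonUDG", "ds_halfUDG", "ss_nonUDG", "ss_halfUDG"):
        raise ValueError(f"unknown protocol {name}")

    nrf = pileup.n_ref_fwd.astype(np.int64).copy()
    nrr = pileup.n_ref_rev.astype(np.int64).copy()
    naf = pileup.n_alt_fwd.astype(np.int64).copy()
    nar = pileup.n_alt_rev.astype(np.int64).copy()

    if name == "ds_nonUDG":
        transition = np.array([s.is_transition for s in sites])
        for arr in (nrf, nrr, naf, nar):
            arr[transition] = 0
    elif name.startswith("ss"):
        is_ct = np.array([s.is_ct for s in sites])
        is_ga = np.array([s.is_ga for s in sites])
        nrf[is_ct] = 0
        naf[is_ct] = 0
        nrr[is_ga] = 0
        nar[is_ga] = 0
    return nrf + nrr, naf + nar


def call_pseudohaploid(
    pileup: LibraryPileup,
    sites: Sequence[SNPSite],
    seed: int,
) -> GenotypeTable:
    """Random-haploid calling: one eligible read per site decides the call."""
    n_ref, n_alt = eligible_counts(pileup, sites)
    total = n_ref + n_alt
    rng = np.random.default_rng(seed)
    calls = np.full(len(sites), MISSING, dtype=np.int8)
    covered = total > 0
    p_alt = np.zeros(len(sites))
    np.divide(n_alt, total, out=p_alt, where=covered)
    draw = rng.random(len(sites)) < p_alt
    calls[covered] = draw[covered].astype(np.int8)
    return GenotypeTable(calls[None, :], [pileup.library_id], "pseudo_haploid")


def call_pseudodiploid(
    pileup: LibraryPileup,
    sites: Sequence[SNPSite],
    seed: int,
) -> GenotypeTable:
    """Random-diploid calling: two reads without replacement per site.

    Sites with fewer than two eligible reads are missing; the genotype is
    the number of alt reads drawn (hypergeometric), so one ref and one alt
    read always yield a het call.
    """
    n_ref, n_alt = eligible_counts(pileup, sites)
    total = n_ref + n_alt
    rng = np.random.default_rng(seed)
    calls = np.full(len(sites), MISSING, dtype=np.int8)
    ok = total >= 2
    if ok.any():
        calls[ok] = rng.hypergeometric(n_alt[ok], n_ref[ok], 2).astype(np.int8)
    return GenotypeTable(calls[None, :], [pileup.library_id], "pseudo_diploid")


def merge_libraries(
    tables: Sequence[GenotypeTable],
    seed: int,
    individual_id: str = "merged",
) -> GenotypeTable:
    """Merge per-library pseudo-haploid calls into one individual.

    Per site, one call is picked uniformly at random among the libraries
    with a non-missing call; sites missing everywhere stay missing.
    """
    if not tables:
        raise ValueError("no genotype tables to merge")
    if any(t.ploidy != "pseudo_haploid" for t in tables):
        raise ValueError("merge_libraries expects pseudo-haploid tables")
    widths = {t.n_sites for t in tables}
    if len(widths) != 1:
        raise ValueError("tables cover different site universes")
    stack = np.vstack([t.data[0] for t in tables])  # (L, S)
    present = stack != MISSING
    n_avail = present.sum(axis=0)
    rng = np.random.default_rng(seed)
    # uniform pick among available calls: rank r in [0, n_avail)
    r = (rng.random(stack.shape[1]) * n_avail).astype(np.int64)
    cum = np.cumsum(present, axis=0) - 1  # rank of each library's call
    chosen = np.full(stack.shape[1], MISSING, dtype=np.int8)
    for lib in range(stack.shape[0]):
        take = present[lib] & (cum[lib] == r)
        chosen[take] = stack[lib, take]
    return GenotypeTable(chosen[None, :], [individual_id], "pseudo_haploid")


def filter_min_snps(
    table: GenotypeTable, min_sites: int = 6000
) -> tuple[list[str], list[str]]:
    """Split individuals into (retained, dropped) by covered-site count.

    Individuals with fewer than ``min_sites`` covered sites are dropped
    (exactly ``min_sites`` is retained).
    """
    counts = table.covered_counts()
    retained = [i for i, c in zip(table.individuals, counts) if c >= min_sites]
    dropped = [i for i, c in zip(table.individuals, counts) if c < min_sites]
    return retained, dropped


@dataclass
class SexAssignment:
    """Genetic sex call from per-library sex-chromosome coverage ratios."""

    x_auto_ratios: list[float]
    y_auto_ratios: list[float]
    call: str  # male | female | unassigned
    used_pmd_filtered: bool = False


def assign_sex(
    lib_coverages: Sequence[dict],
    contamination_flagged: bool = False,
    threshold: float = 0.2,
) -> SexAssignment:
    """Sex from Y/autosome coverage ratios across libraries.

    ``lib_coverages`` holds per-library dicts with keys ``auto``, ``x``,
    ``y`` and optionally ``auto_pmd``, ``x_pmd``, ``y_pmd``.  Male if any
    library's Y/Auto ratio exceeds the threshold; female if all fall below
    it; a ratio exactly at the threshold leaves the call unassigned.  When
    contamination was flagged the rule is re-evaluated on the PMD-filtered
    coverages where available.
    """
    if not lib_coverages:
        raise ValueError("no library coverages supplied")
    use_pmd = contamination_flagged and all(
        "auto_pmd" in lc for lc in lib_coverages
    )
    suffix = "_pmd" if use_pmd else ""
    x_ratios, y_ratios = [], []
    for lc in lib_coverages:
        auto = lc["auto" + suffix]
        if auto <= 0:
            raise ValueError("autosomal coverage must be positive")
        x_ratios.append(lc.get("x" + suffix, 0.0) / auto)
        y_ratios.append(lc["y" + suffix] / auto)
    if any(r > threshold for r in y_ratios):
        call = "male"
    elif all(r < threshold for r in y_ratios):
        call = "female"
    else:
        call = "unassigned"
    return SexAssignment(x_ratios, y_ratios, call, used_pmd_filtered=use_pmd)
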