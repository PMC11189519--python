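"""VCF 4.2, BED, and group-table I/O for the cohort model.

Reading goes through htslib (cyvcf2) and therefore accepts both plain and
bgzip/gzip-compressed VCF. A light structural pre-scan of text input gives
line-numbered parse errors, which htslib does not.

Depth handling: ``mean_depth`` is taken from, in order of preference, the
mean of per-sample FORMAT/DP over called samples, the ``MEANDP`` INFO field
(written by :func:`write_vcf` for lossless round trips), or INFO/DP divided
by the sample count. Records with none of these carry NaN, which the depth
filter treats as passing.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import os
from typing import Iterable

import numpy as np
from cyvcf2 import VCF

from relictpop.variant_store.model import (
    MISSING,
    CohortMatrix,
    GenomicIntervals,
    GroupAssignment,
    SiteRecord,
    UnsupportedPloidyError,
    VcfParseError,
    classify_alleles,
)

logger = logging.getLogger(__name__)

_VCF_FIXED_COLS = 9  # CHROM..FORMAT


def _open_text(path: str) -> io.TextIOBase:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _prescan(path: str) -> None:
    """Structural sanity check producing line-numbered errors."""
    n_samples = None
    saw_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < _VCF_FIXED_COLS:
                    raise VcfParseError(f"line {lineno}: truncated #CHROM header")
                n_samples = len(cols) - _VCF_FIXED_COLS
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise VcfParseError(f"line {lineno}: data before #CHROM header")
            cols = line.rstrip("\n").split("\t")
            if len(cols) != _VCF_FIXED_COLS + n_samples:
                raise VcfParseError(
                    f"line {lineno}: expected {_VCF_FIXED_COLS + n_samples} "
                    f"columns, found {len(cols)}"
                )
            try:
                int(cols[1])
            except ValueError:
                raise VcfParseError(f"line {lineno}: POS {cols[1]!r} is not an integer") from None
    if not saw_header:
        raise VcfParseError("no #CHROM header line found")


def read_vcf(path: str | os.PathLike) -> CohortMatrix:
    """Read an all-sites VCF into a :class:`CohortMatrix`.

    Genotypes are collapsed to alternate-allele dosages; ``./.`` and
    half-calls map to missing. Ploidy other than 2 raises
    :class:`UnsupportedPloidyError`.
    """
    path = os.fspath(path)
    _prescan(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    sites: list[SiteRecord] = []
    dosage_cols: list[np.ndarray] = []
    for rec_idx, v in enumerate(vcf):
        alts = tuple(a for a in (v.ALT or []) if a not in (".", ""))
        col = np.empty(n, dtype=np.int8)
        observed: set[int] = set()
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"record {v.CHROM}:{v.POS}, sample {samples[i]}: "
                    f"ploidy {len(alleles)} unsupported"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING  # includes half-calls like 0/.
                continue
            observed.update(alleles)
            col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        mean_depth = _record_depth(v, n)
        site_class = classify_alleles(v.REF, alts)
        if site_class is None:
            if not any(a > 0 for a in observed):
                site_class = "invariant"
            elif len(observed) > 2:
                site_class = "multiallelic"
            else:
                site_class = "snp"
        sites.append(
            SiteRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_alleles=alts,
                site_id=v.ID,
                mean_depth=mean_depth,
                site_class=site_class,
            )
        )
        dosage_cols.append(col)
    vcf.close()
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.zeros((n, 0), dtype=np.int8)
    )
    m = CohortMatrix(samples=samples, sites=sites, dosages=dosages)
    return m.sorted_by_position()


def _record_depth(v, n_samples: int) -> float:
    try:
        dp = v.format("DP")
    except KeyError:
        dp = None
    if dp is not None:
        dp = np.asarray(dp, dtype=np.float64).reshape(-1)
        valid = dp[(dp >= 0) & np.isfinite(dp)]
        if valid.size:
            return float(valid.mean())
    mdp = v.INFO.get("MEANDP")
    if mdp is not None:
        return float(mdp)
    info_dp = v.INFO.get("DP")
    if info_dp is not None and n_samples > 0:
        return float(info_dp) / n_samples
    return float("nan")


def _genotype_string(d: int) -> str:
    if d < 0:
        return "./."
    return ("0/0", "0/1", "1/1")[d]


def write_vcf(m: CohortMatrix, path: str | os.PathLike, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCF 4.2 file that :func:`read_vcf` inverts.

    Invariant sites get a ``.`` ALT column; missing dosages become ``./.``;
    mean depth is serialized as the ``MEANDP`` INFO field. For multiallelic
    records only the collapsed dosage is representable (dosage 1 -> ``0/1``
    against the first ALT), which is all this model stores.
    """
    path = os.fspath(path)
    if contig_lengths is None:
        contig_lengths = {}
        for s in m.sites:
            contig_lengths[s.chrom] = max(contig_lengths.get(s.chrom, 0), s.pos)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=relictpop\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MEANDP,Number=1,Type=Float,Description="Mean per-sample depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(m.samples) + "\n")
        for j, site in enumerate(m.sites):
            has_alt = site.alt_alleles and site.site_class != "invariant"
            alt = ",".join(site.alt_alleles) if has_alt else "."
            info = (
                f"MEANDP={site.mean_depth:.10g}"
                if math.isfinite(site.mean_depth)
                else "."
            )
            gts = "\t".join(_genotype_string(int(d)) for d in m.dosages[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id or '.'}\t"
                f"{site.ref_allele}\t{alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_bed(path: str | os.PathLike) -> GenomicIntervals:
    """Read 3+ column BED (0-based half-open) into normalized intervals."""
    tuples: list[tuple[str, int, int]] = []
    with _open_text(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 BED columns")
            tuples.append((cols[0], int(cols[1]), int(cols[2])))
    return GenomicIntervals.from_tuples(tuples)


def write_bed(g: GenomicIntervals, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "wt") as fh:
        for chrom in sorted(g.by_chrom):
            for start, end in g.by_chrom[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_groups(path: str | os.PathLike) -> GroupAssignment:
    """Read a two-column sample<TAB>group table."""
    pairs: list[tuple[str, str]] = []
    with _open_text(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}, line {lineno}: expected sample<TAB>group")
            pairs.append((cols[0], cols[1]))
    return GroupAssignment.from_pairs(pairs)


def write_groups(groups: GroupAssignment, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "wt") as fh:
        for sample, label in groups.assignment.items():
            fh.write(f"{sample}\t{label}\n")
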