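"""Readers and writers for the on-disk formats used by the scan.

Formats: PED/MAP linkage text for diploid genotypes, phased VCF for
haplotypes, TSV for outgroup-allele tables and score tables, BED (0-based
half-open) for regions and gene annotation.  Positions are 1-based inclusive
in memory and only converted at the BED boundary.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, CandidateRegion, FormatError, GenotypeMatrix, HaplotypePanel, MarkerMap

_VALID_PED_ALLELES = frozenset("ACGT0")


# ---------------------------------------------------------------------------
# PED / MAP


def read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    """Read a 4-column MAP file (chrom, marker_id, cM, pos_bp)."""
    df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos_bp"],
        dtype={"chrom": str, "marker_id": str},
    )
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise FormatError(f"duplicate marker id {dup!r} in {map_path}")
    return df


def read_ped_map(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    allele_table: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read diploid genotypes from PED/MAP linkage text.

    PED rows carry six leading columns (family, individual, father, mother,
    sex, phenotype) then two allele characters per marker; ``0`` marks a
    missing allele and a call with any missing allele is recorded as missing.
    The family column is taken as the population label.

    Allele coding: if ``allele_table`` (TSV: marker_id, allele1, allele2) is
    given it fixes the coding; otherwise ``allele1`` < ``allele2``
    alphabetically among the alleles observed in the data, and for
    monomorphic markers the unobserved second allele is the first nucleotide
    of A,C,G,T differing from the observed one.  Genotype codes count copies
    of ``allele2``.  Markers out of position order within a chromosome are
    rejected, not sorted.
    """
    mdf = read_map(map_path)
    n_markers = len(mdf)

    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    obs_alleles: list[set[str]] = [set() for _ in range(n_markers)]

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"(6 leading + 2 per marker), got {len(fields)}"
                )
            pops.append(fields[0])
            sample_ids.append(fields[1])
            alleles = fields[6:]
            bad = [a for a in alleles if a not in _VALID_PED_ALLELES]
            if bad:
                raise FormatError(
                    f"{ped_path} line {lineno}: allele code {bad[0]!r} not in A,C,G,T,0"
                )
            rows.append(np.array(alleles, dtype="U1").reshape(n_markers, 2))

    if not rows:
        raise FormatError(f"{ped_path}: no samples")
    allele_pairs = np.stack(rows)  # samples x markers x 2
    for j in range(n_markers):
        seen = set(allele_pairs[:, j, :].ravel())
        seen.discard("0")
        obs_alleles[j] = seen

    if allele_table is not None:
        at = pd.read_csv(allele_table, sep="\t", dtype=str).set_index("marker_id")
        a1 = at.loc[mdf["marker_id"], "allele1"].to_numpy()
        a2 = at.loc[mdf["marker_id"], "allele2"].to_numpy()
    else:
        a1 = np.empty(n_markers, dtype=object)
        a2 = np.empty(n_markers, dtype=object)
        for j, seen in enumerate(obs_alleles):
            s = sorted(seen)
            if len(s) > 2:
                raise FormatError(
                    f"marker {mdf['marker_id'][j]!r}: more than two alleles observed {s}"
                )
            if len(s) == 2:
                a1[j], a2[j] = s
            elif len(s) == 1:
                a1[j] = s[0]
                a2[j] = next(b for b in "ACGT" if b != s[0])
            else:  # fully missing marker
                a1[j], a2[j] = "A", "C"

    markers = MarkerMap(mdf["marker_id"].to_numpy(), mdf["chrom"].to_numpy(), mdf["pos_bp"].to_numpy(), a1, a2)

    calls = np.empty((len(sample_ids), n_markers), dtype=np.int8)
    for j in range(n_markers):
        pair = allele_pairs[:, j, :]
        missing = (pair == "0").any(axis=1)
        known = {a1[j], a2[j], "0"}
        stray = set(pair.ravel()) - known
        if stray:
            raise FormatError(
                f"marker {markers.marker_id[j]!r}: allele {sorted(stray)[0]!r} not in "
                f"declared pair {a1[j]}/{a2[j]}"
            )
        calls[:, j] = (pair == a2[j]).sum(axis=1)
        calls[missing, j] = MISSING

    return GenotypeMatrix(sample_ids, np.array(pops, dtype=object), calls, markers)


def write_ped_map(
    g: GenotypeMatrix,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    allele_table: str | os.PathLike | None = None,
) -> None:
    """Write genotypes as PED/MAP; inverse of :func:`read_ped_map`.

    Heterozygotes are written ``allele1 allele2``, so a round trip through
    ``read_ped_map`` with the same ``allele_table`` reproduces the matrix
    exactly.
    """
    m = g.markers
    with open(map_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chrom[j]}\t{m.marker_id[j]}\t0\t{m.pos_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            lead = [str(g.population_labels[i]), sid, "0", "0", "0", "-9"]
            toks = []
            for j in range(m.n_markers):
                c = g.calls[i, j]
                if c == MISSING:
                    toks += ["0", "0"]
                elif c == 0:
                    toks += [m.allele1[j], m.allele1[j]]
                elif c == 1:
                    toks += [m.allele1[j], m.allele2[j]]
                else:
                    toks += [m.allele2[j], m.allele2[j]]
            fh.write(" ".join(lead + toks) + "\n")
    if allele_table is not None:
        pd.DataFrame(
            {"marker_id": m.marker_id, "allele1": m.allele1, "allele2": m.allele2}
        ).to_csv(allele_table, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phased VCF


def read_phased_vcf(
    vcf_path: str | os.PathLike,
    populations: Mapping[str, str] | None = None,
) -> HaplotypePanel:
    """Read fully phased biallelic SNPs from a VCF into a haplotype panel.

    Every GT must use the phased ``|`` separator with no missing alleles;
    multi-allelic records are rejected.  ``populations`` maps sample id to
    population label (default: one population ``"pop"``).
    """
    sample_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []

    with open(vcf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            if not sample_ids:
                raise FormatError(f"{vcf_path}: record before #CHROM header (line {lineno})")
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{vcf_path} line {lineno}: truncated record")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            where = f"record {chrom}:{pos} ({vid})"
            if "," in alt:
                raise FormatError(f"{vcf_path}: multi-allelic {where}")
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                raise FormatError(f"{vcf_path}: non-SNP alleles at {where}")
            gt_index = f[8].split(":").index("GT")
            col = np.empty(2 * len(sample_ids), dtype=np.uint8)
            for s, cell in enumerate(f[9:]):
                gt = cell.split(":")[gt_index]
                if "/" in gt:
                    raise FormatError(f"{vcf_path}: unphased genotype {gt!r} at {where}, sample {sample_ids[s]}")
                parts = gt.split("|")
                if len(parts) != 2 or parts[0] not in "01" or parts[1] not in "01":
                    raise FormatError(
                        f"{vcf_path}: genotype {gt!r} at {where}, sample {sample_ids[s]} "
                        "(phased input must be complete and biallelic)"
                    )
                col[2 * s] = int(parts[0])
                col[2 * s + 1] = int(parts[1])
            chroms.append(chrom)
            poss.append(pos)
            ids.append(vid if vid != "." else f"{chrom}_{pos}")
            refs.append(ref)
            alts.append(alt)
            cols.append(col)

    if not sample_ids:
        raise FormatError(f"{vcf_path}: missing #CHROM header")
    markers = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(poss), np.array(refs, dtype=object), np.array(alts, dtype=object))
    alleles = np.column_stack(cols) if cols else np.empty((2 * len(sample_ids), 0), dtype=np.uint8)
    if populations is None:
        pops = np.array(["pop"] * len(sample_ids), dtype=object)
    else:
        pops = np.array([populations[s] for s in sample_ids], dtype=object)
    return HaplotypePanel(sample_ids, pops, alleles, markers)


def write_phased_vcf(panel: HaplotypePanel, vcf_path: str | os.PathLike) -> None:
    """Write a haplotype panel as a minimal phased VCF (GT only)."""
    m = panel.markers
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ehhscan\n")
        for c in pd.unique(m.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids) + "\n")
        a = panel.alleles
        for j in range(m.n_markers):
            gts = "\t".join(f"{a[2 * i, j]}|{a[2 * i + 1, j]}" for i in range(panel.n_samples))
            fh.write(
                f"{m.chrom[j]}\t{m.pos_bp[j]}\t{m.marker_id[j]}\t{m.allele1[j]}\t{m.allele2[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Outgroup tables, sample lists

#: On-disk token for a missing outgroup call.
OUTGROUP_MISSING = "."


def read_outgroup_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an outgroup-allele TSV (marker_id, one column per species).

    Returns a DataFrame indexed by marker_id with one single-letter allele
    (or NaN for missing) per species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("marker_id")
    df = df.replace(OUTGROUP_MISSING, np.nan)
    for col in df.columns:
        bad = df[col].dropna()[~df[col].dropna().isin(list("ACGT"))]
        if len(bad):
            raise FormatError(f"{path}: invalid outgroup allele {bad.iloc[0]!r} for species {col}")
    return df


def write_outgroup_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.fillna(OUTGROUP_MISSING).to_csv(path, sep="\t", index=True, index_label="marker_id")


def write_sample_list(sample_ids: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)


def read_gene_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene-annotation BED file (chrom, start, end, name)."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path} line {lineno}: expected >=4 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path} line {lineno}: non-integer coordinate") from e
            if start >= end:
                raise FormatError(f"{path} line {lineno}: start >= end")
            recs.append((f[0], start, end, f[3]))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | os.PathLike) -> None:
    """Write candidate regions as BED with method/n_sig/peak columns."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (str(r.chrom), r.start)):
            methods = ",".join(sorted(r.methods)) or "."
            peak = f"{r.peak_pscore:.4f}" if np.isfinite(r.peak_pscore) else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{methods}\t{r.n_sig}\t{peak}\n")


def read_regions_bed(path: str | os.PathLike) -> list[CandidateRegion]:
    """Read regions written by :func:`write_regions_bed` back to memory."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path} line {lineno}: expected 6 columns")
            methods = frozenset() if f[3] == "." else frozenset(f[3].split(","))
            peak = float("nan") if f[5] == "." else float(f[5])
            out.append(
                CandidateRegion(f[0], int(f[1]) + 1, int(f[2]), methods, int(f[4]), peak)
            )
    return out


# ---------------------------------------------------------------------------
# Score tables


def write_score_table(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_score_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
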