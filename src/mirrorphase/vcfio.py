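"""VCF and sidecar-format readers and writers.

VCF is the interchange format: unphased GT for study genotypes, phased GT
(``|``) for haplotypes, with haplotype 1 consistently left of the bar —
phase continuity across markers is the payload.  Genetic-map positions ride
in an INFO ``CM`` field.  A minimal haplotype-matrix text format (paired
lines of 0/1 strings) is provided for tests and docs, and the simulator's
pedigree travels as a tab-separated sidecar.

Coordinates are 1-based in files (VCF convention) and 0-based in memory;
this module is the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .model import MISSING, GenotypeMatrix, InputError, MarkerMap

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mirrorphase {version}{extra}
##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position in centimorgans">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _scan_vcf(path: str):
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    offenders = []
    positions = set()
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            offenders.append(f"{var.CHROM}:{var.POS} ({var.REF}->{','.join(var.ALT) or '.'})")
            continue
        if var.POS in positions:
            raise InputError(f"duplicated position {var.CHROM}:{var.POS}")
        positions.add(var.POS)
        rows.append(var)
    if offenders:
        raise InputError(
            "only biallelic SNP records are supported; offending records: "
            + ", ".join(offenders[:20])
            + ("..." if len(offenders) > 20 else "")
        )
    if not rows:
        raise InputError(f"no usable variant records in {path}")
    return samples, rows


def _marker_map(rows) -> MarkerMap:
    ids = np.array([r.ID or f"{r.CHROM}:{r.POS}" for r in rows], dtype=object)
    bp = np.array([r.POS for r in rows], dtype=np.int64)
    cm = np.array([r.INFO.get("CM", i * 0.01) for i, r in enumerate(rows)],
                  dtype=float)
    return MarkerMap(ids, bp, cm)


def read_genotypes_vcf(path: str) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read unphased (or phased) genotypes as dosages; ``./.`` -> missing."""
    samples, rows = _scan_vcf(path)
    m = len(rows)
    n = len(samples)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j, var in enumerate(rows):
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                dosage[i, j] = a + b
    mask = np.nonzero((dosage == MISSING).all(axis=0))[0]
    return GenotypeMatrix(dosage=dosage, mask=mask, sample_ids=samples), _marker_map(rows)


def read_haplotypes_vcf(path: str) -> tuple[np.ndarray, MarkerMap, list[str]]:
    """Read phased haplotypes as an (N, 2, M) array; every GT must be phased."""
    samples, rows = _scan_vcf(path)
    m = len(rows)
    n = len(samples)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    for j, var in enumerate(rows):
        for i, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise InputError(
                    f"missing genotype for sample {samples[i]} at record "
                    f"{var.CHROM}:{var.POS}; phased haplotype input must be complete"
                )
            if not phased:
                raise InputError(
                    f"unphased genotype for sample {samples[i]} at record "
                    f"{var.CHROM}:{var.POS}; expected '|' separators"
                )
            haps[i, 0, j] = a
            haps[i, 1, j] = b
    return haps, _marker_map(rows), samples


def _header(extra_meta: dict | None, timestamp: bool) -> str:
    import datetime

    parts = []
    for k, v in (extra_meta or {}).items():
        parts.append(f"##{k}={v}")
    if timestamp:
        parts.append("##filedate=" + datetime.date.today().strftime("%Y%m%d"))
    extra = ""
    head = _VCF_HEADER.format(version=__version__, extra=extra)
    if parts:
        head += "\n".join(parts) + "\n"
    return head


def write_genotypes_vcf(path: str, genotypes: GenotypeMatrix, markers: MarkerMap,
                        extra_meta: dict | None = None,
                        timestamp: bool = False) -> None:
    """Write unphased dosages (``0/0``, ``0/1``, ``1/1``; missing ``./.``)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_header(extra_meta, timestamp))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for j in range(markers.n_markers):
            cols = ["1", str(int(markers.position_bp[j])), str(markers.marker_id[j]),
                    "A", "G", ".", "PASS", f"CM={markers.position_cm[j]:g}", "GT"]
            cols += [gt_str[int(d)] for d in genotypes.dosage[:, j]]
            fh.write("\t".join(cols) + "\n")


def write_phased_vcf(path: str, haplotypes: np.ndarray, markers: MarkerMap,
                     sample_ids: list[str] | None = None,
                     missing_sites: np.ndarray | None = None,
                     extra_meta: dict | None = None,
                     timestamp: bool = False) -> None:
    """Write an (N, 2, M) haplotype array with phased GT.

    ``missing_sites`` (an (N, M) boolean array) marks entries to emit as
    ``./.`` instead of a call — used when masked sites were *not* imputed.
    """
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n, _, m = haplotypes.shape
    if markers.n_markers != m:
        raise InputError("haplotypes and marker map disagree on marker count")
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(_header(extra_meta, timestamp))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(m):
            cols = ["1", str(int(markers.position_bp[j])), str(markers.marker_id[j]),
                    "A", "G", ".", "PASS", f"CM={markers.position_cm[j]:g}", "GT"]
            for i in range(n):
                if missing_sites is not None and missing_sites[i, j]:
                    cols.append("./.")
                else:
                    cols.append(f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}")
            fh.write("\t".join(cols) + "\n")


def write_hap_matrix(path: str, haplotypes: np.ndarray) -> None:
    """Minimal text format: one haplotype per line as a 0/1 string, paired
    lines per individual."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    with open(path, "w") as fh:
        for pair in haplotypes:
            for hap in pair:
                fh.write("".join(str(int(a)) for a in hap) + "\n")


def read_hap_matrix(path: str) -> np.ndarray:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) % 2:
        raise InputError("haplotype matrix must contain an even number of lines")
    haps = np.array([[int(c) for c in ln] for ln in lines], dtype=np.int8)
    if not np.isin(haps, [0, 1]).all():
        raise InputError("haplotype matrix entries must be 0 or 1")
    return haps.reshape(len(lines) // 2, 2, -1)


def write_pedigree(path: str, pedigree: pd.DataFrame,
                   sample_ids: list[str]) -> None:
    """Tab-separated pedigree sidecar: individual, father, mother, twin_of."""
    def name(idx: int) -> str:
        return sample_ids[idx] if idx >= 0 else "."

    out = pd.DataFrame({
        "individual": [sample_ids[i] for i in pedigree["individual"]],
        "father": [name(i) for i in pedigree["father"]],
        "mother": [name(i) for i in pedigree["mother"]],
        "twin_of": [name(i) for i in pedigree["twin_of"]],
    })
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
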