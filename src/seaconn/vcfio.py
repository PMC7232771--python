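"""Minimal VCF 4.2 and site-metadata I/O for simulated genotype datasets.

Writing emits a plain-text, GT-only VCF (CHROM, POS, ID, REF, ALT, QUAL,
FILTER, INFO, FORMAT=GT).  Reading uses cyvcf2 and accepts any biallelic
SNP VCF with GT; multi-allelic records are rejected by id.  Sample names
follow ``<site_id>_<k>``; site metadata comes from a CSV table with columns
site_id, x_km, y_km, region, salinity_psu, temp_C, mpa.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeDataset

SITE_COLUMNS = ["site_id", "x_km", "y_km", "region", "salinity_psu", "temp_C", "mpa"]

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.reset_index().rename(columns={"index": "site_id"}).to_csv(path, index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df.set_index("site_id")


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as a minimal uncompressed VCF 4.2 (GT only).

    Loci are placed on a synthetic chromosome "1" at consecutive positions;
    REF/ALT are fixed placeholder alleles (dosage is what the pipeline
    consumes).
    """
    path = Path(path)
    G = dataset.genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=seaconn\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples) + "\n")
        for j, locus in enumerate(dataset.locus_ids):
            gts = "\t".join(_GT_STRING[int(g)] for g in G[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(
    path: str | Path,
    sites: pd.DataFrame,
    sample_site: dict | None = None,
) -> GenotypeDataset:
    """Read biallelic SNP genotypes (GT) into a :class:`GenotypeDataset`.

    ``sites`` is the site-metadata table (indexed by site_id).  Samples are
    mapped to sites by ``sample_site`` if given, otherwise by splitting the
    sample name at its last underscore.  Raises on non-biallelic records
    (listing the record) and on samples without site metadata.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)

    if sample_site is None:
        sample_site = {}
        for s in samples:
            if "_" not in s:
                raise ValueError(
                    f"cannot infer site for sample {s!r}; pass sample_site")
            sample_site[s] = s.rsplit("_", 1)[0]
    site_index = set(sites.index)
    unknown = [s for s in samples if sample_site[s] not in site_index]
    if unknown:
        raise ValueError(
            f"samples with no site metadata: {unknown} "
            f"(site table has {sorted(map(str, site_index))})")

    dosages, locus_ids = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            raise ValueError(
                f"non-biallelic record rejected: {rid} (ALT={rec.ALT})")
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for k, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                row[k] = a + b
        dosages.append(row)
        locus_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if not dosages:
        raise ValueError(f"no records in {path}")

    # site table restricted/ordered to the sites actually sampled
    seen_sites = []
    for s in samples:
        site = sample_site[s]
        if site not in seen_sites:
            seen_sites.append(site)
    return GenotypeDataset(
        genotypes=np.asarray(dosages, dtype=np.int8).T,
        samples=samples,
        sample_site=pd.Series([sample_site[s] for s in samples], index=samples,
                              name="site_id"),
        sites=sites.loc[seen_sites],
        locus_ids=locus_ids,
        meta={"source": path},
    )
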