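"""Text-file formats shared by every stage of the pipeline.

All tabular data are plain TSV.  The pedigree uses the 6-column FAM
dialect (family/breed, id, sire, dam, sex, phenotype placeholder);
unknown parents are written as ``0``.  Genotypes are allele counts
0/1/2 with ``-1`` for missing.  Recombination-map files follow the
layout: SNP name, chromosome, base-pair position, then one rate column
per breed x sex, where the rate on a row belongs to the interval
between that SNP and the preceding SNP on the same chromosome (the
first SNP of each chromosome carries rate 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENO_MISSING = -1
_VALID_GENO = frozenset((-1, 0, 1, 2))

SEX_TO_FAM = {"M": 1, "F": 2, "U": 0}
FAM_TO_SEX = {v: k for k, v in SEX_TO_FAM.items()}


class FormatError(ValueError):
    """A file violated the format contract (with row/column context)."""


class MarkerMap:
    """Ordered SNP metadata for a set of autosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``name``, ``chrom`` (integer label), ``bp`` (1-based
        position).  Rows must be in genome order: chromosomes in
        contiguous blocks, positions strictly increasing within a
        chromosome.

    Notes
    -----
    Interval convention: interval *i* covers ``(bp[i-1], bp[i]]`` on the
    same chromosome and is stored on the row of SNP *i*; the first SNP
    of every chromosome has no interval.  ``has_interval`` masks the
    rows that do.
    """

    def __init__(self, table: pd.DataFrame):
        missing = {"name", "chrom", "bp"} - set(table.columns)
        if missing:
            raise FormatError(f"marker table lacks columns {sorted(missing)}")
        table = table.reset_index(drop=True)
        self.table = table
        self.name = table["name"].astype(str).to_numpy()
        self.chrom = table["chrom"].to_numpy(dtype=np.int64)
        self.bp = table["bp"].to_numpy(dtype=np.int64)
        n = len(table)
        if n == 0:
            raise FormatError("marker table is empty")

        first = np.zeros(n, dtype=bool)
        first[0] = True
        first[1:] = self.chrom[1:] != self.chrom[:-1]
        chrom_ids = self.chrom[first]
        if len(np.unique(chrom_ids)) != len(chrom_ids):
            raise FormatError("chromosome rows are not contiguous blocks")
        d = np.diff(self.bp)
        bad = np.flatnonzero(~first[1:] & (d <= 0))
        if bad.size:
            r = int(bad[0]) + 1
            raise FormatError(
                f"bp positions not strictly increasing at row {r} "
                f"(chrom {self.chrom[r]}, bp {self.bp[r - 1]} -> {self.bp[r]})"
            )
        self.first_of_chrom = first
        self.has_interval = ~first
        width = np.zeros(n, dtype=np.int64)
        width[1:] = d
        width[first] = 0
        self.interval_bp = width

        self.chrom_ids = chrom_ids
        self.chrom_start_row = np.flatnonzero(first)
        ends = np.r_[self.chrom_start_row[1:], n]
        self.chrom_end_row = ends
        self.chrom_length_bp = self.bp[ends - 1]
        # cumulative genome coordinate (gap of 1 bp between chromosomes)
        offsets = np.r_[0, np.cumsum(self.chrom_length_bp[:-1] + 1)]
        self._chrom_offset = dict(zip(chrom_ids.tolist(), offsets.tolist()))
        row_chrom_index = np.cumsum(first) - 1
        self.genome_bp = offsets[row_chrom_index] + self.bp

    @property
    def n_snps(self) -> int:
        return len(self.bp)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_ids)

    @property
    def n_intervals(self) -> int:
        return int(self.has_interval.sum())

    def chrom_slices(self):
        """Yield ``(chrom_id, slice)`` pairs in genome order."""
        for cid, a, b in zip(self.chrom_ids, self.chrom_start_row, self.chrom_end_row):
            yield int(cid), slice(int(a), int(b))

    def genome_coord(self, chrom: np.ndarray, bp: np.ndarray) -> np.ndarray:
        off = np.array([self._chrom_offset[int(c)] for c in np.atleast_1d(chrom)])
        return off + np.atleast_1d(bp)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MarkerMap)
            and self.n_snps == other.n_snps
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.bp == other.bp))
            and bool(np.all(self.name == other.name))
        )


@dataclass
class Cohort:
    """Pedigree + marker metadata + genotype matrix.

    ``ped`` is indexed by animal id with columns ``sire``, ``dam``
    (``"0"`` = unknown/founder), ``sex`` (``"M"``/``"F"``/``"U"``) and
    ``breed``.  ``genotypes`` rows align with ``ids``; every id in
    ``ids`` must appear in ``ped``.
    """

    ped: pd.DataFrame
    markers: MarkerMap
    genotypes: np.ndarray
    ids: np.ndarray

    _row_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        if self.genotypes.shape != (len(self.ids), self.markers.n_snps):
            raise FormatError(
                f"genotype matrix is {self.genotypes.shape}, expected "
                f"({len(self.ids)}, {self.markers.n_snps})"
            )
        unknown = set(self.ids) - set(self.ped.index)
        if unknown:
            raise FormatError(f"genotyped ids missing from pedigree: {sorted(unknown)[:5]}")
        self._row_of = {a: i for i, a in enumerate(self.ids)}

    @property
    def typed_counts(self) -> np.ndarray:
        """Observed (non-missing) marker count per genotyped animal."""
        return (self.genotypes != GENO_MISSING).sum(axis=1)

    def is_genotyped(self, animal: str) -> bool:
        return animal in self._row_of

    def genotypes_of(self, animal: str) -> np.ndarray:
        return self.genotypes[self._row_of[animal]]

    def typed_count_of(self, animal: str) -> int:
        return int((self.genotypes_of(animal) != GENO_MISSING).sum())


# ---------------------------------------------------------------------------
# cohort readers / writers

def write_cohort(cohort: Cohort, outdir, prefix: str = "cohort") -> dict:
    """Write pedigree (.fam), SNP metadata and genotype matrix TSVs.

    Returns the mapping of logical name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / f"{prefix}.fam",
        "snps": outdir / f"{prefix}.snps.tsv",
        "genotypes": outdir / f"{prefix}.genotypes.tsv",
    }
    ped = cohort.ped
    fam = pd.DataFrame(
        {
            "family": ped["breed"].astype(str),
            "id": ped.index.astype(str),
            "sire": ped["sire"].astype(str),
            "dam": ped["dam"].astype(str),
            "sex": [SEX_TO_FAM.get(s, 0) for s in ped["sex"]],
            "phenotype": -9,
        }
    )
    fam.to_csv(paths["pedigree"], sep="\t", header=False, index=False)
    cohort.markers.table[["name", "chrom", "bp"]].to_csv(paths["snps"], sep="\t", index=False)
    geno = pd.DataFrame(cohort.genotypes, columns=cohort.markers.name)
    geno.insert(0, "id", cohort.ids)
    geno.to_csv(paths["genotypes"], sep="\t", index=False)
    return paths


def read_markers(snp_path) -> MarkerMap:
    table = pd.read_csv(snp_path, sep="\t", comment="#")
    return MarkerMap(table)


def read_cohort(pedigree_path, snp_path, genotype_path) -> Cohort:
    """Read the three cohort files and validate their mutual consistency."""
    markers = read_markers(snp_path)

    fam = pd.read_csv(
        pedigree_path,
        sep=r"\s+",
        header=None,
        names=["family", "id", "sire", "dam", "sex", "phenotype"],
        dtype=str,
        comment="#",
    )
    ped = pd.DataFrame(
        {
            "sire": fam["sire"].values,
            "dam": fam["dam"].values,
            "sex": [FAM_TO_SEX.get(int(s), "U") for s in fam["sex"]],
            "breed": fam["family"].values,
        },
        index=pd.Index(fam["id"].values, name="id"),
    )
    if ped.index.duplicated().any():
        dup = ped.index[ped.index.duplicated()][0]
        raise FormatError(f"duplicate animal id in pedigree: {dup}")

    geno_df = pd.read_csv(genotype_path, sep="\t", comment="#")
    if geno_df.columns[0] != "id":
        raise FormatError("genotype matrix must start with an 'id' column")
    ids = geno_df["id"].astype(str).to_numpy()
    mat = geno_df.drop(columns="id")
    if mat.shape[1] != markers.n_snps:
        raise FormatError(
            f"genotype matrix has {mat.shape[1]} SNP columns, "
            f"marker table has {markers.n_snps}"
        )
    G = mat.to_numpy()
    bad = ~np.isin(G, (-1, 0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"illegal genotype value {G[r, c]!r} at row {r} (animal {ids[r]}), "
            f"column {c} (SNP {markers.name[c]})"
        )
    return Cohort(ped=ped, markers=markers, genotypes=G.astype(np.int8), ids=ids)


# ---------------------------------------------------------------------------
# recombination-map files

def write_recmap(maps, path) -> None:
    """Write one or more recombination maps to a single TSV.

    ``maps`` is a sequence of :class:`pedigrec.maps.RecombinationMap`;
    rate columns appear in the caller-given order labelled
    ``<breed>_<sex>``.  All maps must share the same marker set.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to write")
    mk = maps[0].markers
    for m in maps[1:]:
        if m.markers != mk:
            raise ValueError("maps built on different SNP sets cannot share a file")
    out = mk.table[["name", "chrom", "bp"]].copy()
    for m in maps:
        out[f"{m.breed}_{m.sex}"] = m.rates
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_recmap(path):
    """Read a recombination-map TSV -> ``(MarkerMap, {label: rates})``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    markers = MarkerMap(df[["name", "chrom", "bp"]])
    rate_cols = [c for c in df.columns if c not in ("name", "chrom", "bp")]
    rates = {c: df[c].to_numpy(dtype=float) for c in rate_cols}
    for label, r in rates.items():
        if (r < 0).any():
            raise FormatError(f"negative rate in column {label}")
    return markers, rates
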