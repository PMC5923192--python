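"""Crossover detection in donor meioses.

For each three-generation family the donor parent is phased against its
own parents and the offspring against both of its parents.  At every
informative site (donor heterozygous and phased) the offspring's
transmitted allele identifies which donor haplotype it inherited; a
crossover is a switch in the matched haplotype between two consecutive
informative sites.  Runs of matches shorter than the minimum flanking
support are treated as genotyping artifacts: their sites are masked and
tracing repeated.  Each accepted crossover is assigned evenly (mass
1/k) to the k adjacent-SNP intervals between its two flanking
informative sites.

Resolution caveats, inherent to the design rather than implementation
choices: crossovers beyond a donor's terminal informative site are
undetectable, and an even number of crossovers between two consecutive
informative sites cancels (only the parity of the local crossover count
is observable).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QcConfig
from .families import FamilyRecord
from .io import Cohort
from .phasing import PhasedPair, UNKNOWN, informative_mask, phase_trio


@dataclass
class MeiosisRecord:
    """Detected crossovers of one donor -> offspring meiosis.

    ``interval_rows``/``masses`` hold the sparse per-SNP-interval
    fractional crossover mass (rows index the marker table; mass sums
    to ``n_crossovers`` up to float rounding).
    """

    donor: str
    offspring: str
    sex: str
    breed: str
    interval_rows: np.ndarray
    masses: np.ndarray
    n_crossovers: int
    donor_informative: int
    offspring_informative: int
    density: int                      # min typed-marker count of the pair
    switch_sites: list = field(default_factory=list, repr=False)
    used_rows: np.ndarray | None = field(default=None, repr=False)

    @property
    def meiosis_id(self) -> str:
        return f"{self.donor}>{self.offspring}"

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


def trace_crossovers(transmitted: np.ndarray, donor: PhasedPair,
                     sites: np.ndarray, min_support: int = 2):
    """Trace template switches along one chromosome.

    Parameters
    ----------
    transmitted : allele vector of the offspring haplotype inherited
        from the donor (``-1`` unknown).
    donor : the donor's phased haplotype pair.
    sites : ordered indices of the donor's informative sites on this
        chromosome.  Sites where the transmitted allele is unknown are
        skipped.
    min_support : runs of fewer consecutive same-template matches are
        masked as genotyping error and tracing repeated.

    Returns ``(switches, used_sites)`` where each switch is an index
    pair ``(a, b)`` of consecutive surviving informative sites whose
    matched donor haplotype differs.
    """
    sites = np.asarray(sites)
    usable = sites[transmitted[sites] != UNKNOWN]
    if usable.size < 2:
        return [], usable
    # donor is heterozygous at informative sites, so the transmitted
    # allele matches exactly one haplotype: True = first haplotype
    match = transmitted[usable] == donor.paternal[usable]

    active = np.ones(usable.size, dtype=bool)
    while True:
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        lab = match[idx]
        bounds = np.r_[0, np.flatnonzero(lab[1:] != lab[:-1]) + 1, lab.size]
        lengths = np.diff(bounds)
        if lengths.size == 1:
            break
        short = np.flatnonzero(lengths < min_support)
        if short.size == 0:
            break
        if short.size == lengths.size:
            active[idx] = False
            break
        for s in short:
            active[idx[bounds[s]:bounds[s + 1]]] = False

    idx = np.flatnonzero(active)
    kept = usable[idx]
    lab = match[idx]
    switch_at = np.flatnonzero(lab[1:] != lab[:-1])
    switches = [(int(kept[j]), int(kept[j + 1])) for j in switch_at]
    return switches, kept


def assign_crossover_mass(switch: tuple, out_rows: list, out_masses: list) -> None:
    """Distribute one crossover evenly over the SNP intervals it spans.

    ``switch`` is a pair of marker-row indices ``(a, b)`` of the two
    flanking informative sites; interval row ``i`` covers
    ``(bp[i-1], bp[i]]``, so the spanned rows are ``a+1 .. b``.
    """
    a, b = switch
    k = b - a
    assert k >= 1, "flanking informative sites must be distinct"
    out_rows.extend(range(a + 1, b + 1))
    out_masses.extend([1.0 / k] * k)


def analyze_family(cohort: Cohort, fam: FamilyRecord, qc: QcConfig,
                   keep_sites: bool = False):
    """Phase and trace one family; ``None`` if the donor fails Mendel QC."""
    mk = cohort.markers
    donor_g = cohort.genotypes_of(fam.donor)
    gp_g = {}
    drow = cohort.ped.loc[fam.donor]
    for role, gp in (("sire", drow["sire"]), ("dam", drow["dam"])):
        gp_g[role] = cohort.genotypes_of(gp) if gp in fam.grandparents else None
    donor_pp = phase_trio(donor_g, gp_g["sire"], gp_g["dam"])

    typed = int((donor_g != -1).sum())
    if typed and donor_pp.n_mendel_errors / typed > qc.max_mendel_rate:
        return None

    orow = cohort.ped.loc[fam.offspring]
    off_g = cohort.genotypes_of(fam.offspring)
    sire_g = cohort.genotypes_of(orow["sire"]) if cohort.is_genotyped(orow["sire"]) else None
    dam_g = cohort.genotypes_of(orow["dam"]) if cohort.is_genotyped(orow["dam"]) else None
    off_pp = phase_trio(off_g, sire_g, dam_g)
    transmitted = off_pp.paternal if fam.donor_sex == "M" else off_pp.maternal

    info = informative_mask(donor_pp)
    rows_list, masses_list, switch_sites = [], [], []
    used_all = []
    for _, sl in mk.chrom_slices():
        sites = np.flatnonzero(info[sl]) + sl.start
        switches, used = trace_crossovers(transmitted, donor_pp, sites,
                                          min_support=qc.min_support)
        for sw in switches:
            assign_crossover_mass(sw, rows_list, masses_list)
        switch_sites.extend(switches)
        if keep_sites:
            used_all.append(used)

    used_known = int((transmitted[info] != UNKNOWN).sum())
    return MeiosisRecord(
        donor=fam.donor,
        offspring=fam.offspring,
        sex=fam.donor_sex,
        breed=fam.breed,
        interval_rows=np.asarray(rows_list, dtype=np.int32),
        masses=np.asarray(masses_list, dtype=float),
        n_crossovers=len(switch_sites),
        donor_informative=int(info.sum()),
        offspring_informative=used_known,
        density=fam.min_typed,
        switch_sites=switch_sites,
        used_rows=np.concatenate(used_all) if keep_sites and used_all else None,
    )


def detect_meioses(cohort: Cohort, families, qc: QcConfig | None = None,
                   keep_sites: bool = False):
    """Run detection over all families.

    Returns ``(records, dropped)`` where ``dropped`` lists families whose
    donor exceeded the Mendelian-error threshold.
    """
    qc = qc or QcConfig()
    records, dropped = [], []
    for fam in families:
        rec = analyze_family(cohort, fam, qc, keep_sites=keep_sites)
        if rec is None:
            dropped.append(fam.meiosis_id)
        else:
            records.append(rec)
    return records, dropped


def qc_filter_meioses(records, qc: QcConfig | None = None):
    """Remove meioses with more than ``qc.max_crossovers`` genome-wide.

    The boundary is retained ("more than" is strict).  Returns
    ``(kept, log)`` with the exclusion log as a DataFrame.
    """
    qc = qc or QcConfig()
    kept, removed = [], []
    for r in records:
        if r.n_crossovers > qc.max_crossovers:
            removed.append({"meiosis": r.meiosis_id, "sex": r.sex,
                            "breed": r.breed, "n_crossovers": r.n_crossovers})
        else:
            kept.append(r)
    log = pd.DataFrame(removed, columns=["meiosis", "sex", "breed", "n_crossovers"])
    return kept, log


def records_to_frame(records) -> pd.DataFrame:
    """Sparse triplet TSV form: meiosis, interval row, mass."""
    parts = []
    for r in records:
        parts.append(pd.DataFrame({
            "meiosis": r.meiosis_id,
            "interval_row": r.interval_rows,
            "mass": r.masses,
        }))
    if not parts:
        return pd.DataFrame(columns=["meiosis", "interval_row", "mass"])
    return pd.concat(parts, ignore_index=True)


def records_from_frames(sparse: pd.DataFrame, meta: pd.DataFrame):
    """Rebuild MeiosisRecords from the TSV frames written by ``detect``."""
    by_meiosis = dict(tuple(sparse.groupby("meiosis"))) if len(sparse) else {}
    records = []
    for _, m in meta.iterrows():
        part = by_meiosis.get(m["meiosis"])
        rows = (part["interval_row"].to_numpy(np.int32)
                if part is not None else np.empty(0, np.int32))
        masses = (part["mass"].to_numpy(float)
                  if part is not None else np.empty(0, float))
        records.append(MeiosisRecord(
            donor=m["donor"], offspring=m["offspring"], sex=m["sex"],
            breed=m["breed"], interval_rows=rows, masses=masses,
            n_crossovers=int(m["n_crossovers"]),
            donor_informative=int(m["donor_informative"]),
            offspring_informative=int(m["offspring_informative"]),
            density=int(m["density"]),
        ))
    return records


def records_meta_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "meiosis": r.meiosis_id, "donor": r.donor, "offspring": r.offspring,
        "sex": r.sex, "breed": r.breed, "n_crossovers": r.n_crossovers,
        "donor_informative": r.donor_informative,
        "offspring_informative": r.offspring_informative,
        "density": r.density,
    } for r in records])
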