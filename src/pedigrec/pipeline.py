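"""End-to-end orchestration: families -> detect -> QC -> maps ->
hotspots -> compare -> phenotypes -> GWAS.

Each stage writes its outputs (TSV with a commented header recording
package version, seed and config hash) before the next starts; reruns
with the same config and inputs are byte-identical.  All counts at
every filtering step are recorded in the run log.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import HotspotCriteria, QcConfig, SimConfig, sim_config_from_yaml
from .crossover import detect_meioses, qc_filter_meioses, records_meta_frame, \
    records_to_frame
from .families import extract_families
from .gwas import RecombinationGwas
from .hotspots import call_hotspots, hotspot_sharing, hotspots_to_frame
from .io import Cohort, read_cohort, write_cohort, write_recmap
from .maps import build_recmap, map_correlation, position_profile
from .phenotypes import adjusted_recombination_rate, hotspot_usage
from .compare import interval_chisq_scan
from .sim import simulate_cohort


@dataclass
class PipelineConfig:
    """Inputs, thresholds and selections for a full run."""

    outdir: str
    seed: int
    sim: SimConfig | None = None          # simulate when set ...
    pedigree: str | None = None           # ... else read these three files
    snps: str | None = None
    genotypes: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    hotspot: HotspotCriteria = field(default_factory=HotspotCriteria)
    density_threshold: int = 0            # marker count for the >=50K class
    map_density_class: str = "ge"         # maps built from this class only
    alpha_compare: float = 0.05
    alpha_gwas: float = 0.05
    breeds: tuple | None = None           # None = all present
    sexes: tuple = ("M", "F")
    kinship: str = "grm"

    def config_hash(self) -> str:
        d = asdict(self)
        for key in ("outdir", "pedigree", "snps", "genotypes"):
            d.pop(key, None)     # paths do not affect the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


def pipeline_config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "sim" in raw and raw["sim"] is not None:
        sim = dict(raw["sim"])
        sim.setdefault("seed", raw.get("seed"))
        if "breeds" in sim:
            sim["breeds"] = tuple(sim["breeds"])
        if "panels" in sim:
            sim["panels"] = tuple(tuple(p) for p in sim["panels"])
        raw["sim"] = SimConfig(**sim)
    if "qc" in raw:
        raw["qc"] = QcConfig(**raw["qc"])
    if "hotspot" in raw:
        raw["hotspot"] = HotspotCriteria(**raw["hotspot"])
    if "breeds" in raw and raw["breeds"] is not None:
        raw["breeds"] = tuple(raw["breeds"])
    if "sexes" in raw:
        raw["sexes"] = tuple(raw["sexes"])
    return PipelineConfig(**raw)


def _write(df: pd.DataFrame, path: Path, header: str, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of key outputs and the log."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# pedigrec {__version__} seed={config.seed} "
              f"config={config.config_hash()}\n")
    log: list[str] = []

    def logline(msg):
        log.append(msg)

    # --- inputs -----------------------------------------------------------
    if config.sim is not None:
        sim = simulate_cohort(config.sim)
        cohort: Cohort = sim.cohort
        write_cohort(cohort, out, prefix="cohort")
        sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        logline(f"simulated cohort: {len(cohort.ids)} animals, "
                f"{cohort.markers.n_snps} SNPs, {len(sim.truth)} true crossovers")
    else:
        if not (config.pedigree and config.snps and config.genotypes):
            raise ValueError("either a sim config or the three input paths are required")
        cohort = read_cohort(config.pedigree, config.snps, config.genotypes)
        logline(f"read cohort: {len(cohort.ids)} animals, "
                f"{cohort.markers.n_snps} SNPs")

    density_threshold = config.density_threshold
    if density_threshold <= 0:
        # default: three quarters of the full panel counts as high density
        density_threshold = int(0.75 * cohort.markers.n_snps)

    # --- families ---------------------------------------------------------
    fams, summary = extract_families(cohort, density_threshold)
    if config.breeds is not None:
        fams = [f for f in fams if f.breed in config.breeds]
    fams = [f for f in fams if f.donor_sex in config.sexes]
    _write(summary, out / "families_summary.tsv", header, index=True)
    fam_df = pd.DataFrame([{
        "offspring": f.offspring, "donor": f.donor, "donor_sex": f.donor_sex,
        "breed": f.breed, "min_typed": f.min_typed,
        "density_class": f.density_class(density_threshold),
    } for f in fams])
    _write(fam_df, out / "families.tsv", header)
    logline(f"three-generation families: {len(fams)} "
            f"(density threshold {density_threshold} markers)")

    # --- detection + QC ---------------------------------------------------
    records, mendel_dropped = detect_meioses(cohort, fams, config.qc)
    logline(f"meioses traced: {len(records)}; dropped for Mendelian errors: "
            f"{len(mendel_dropped)}")
    records, qc_log = qc_filter_meioses(records, config.qc)
    _write(qc_log, out / "qc_excluded.tsv", header)
    logline(f"meioses after >{config.qc.max_crossovers}-crossover QC: {len(records)}")
    _write(records_to_frame(records), out / "meioses_sparse.tsv", header)
    _write(records_meta_frame(records), out / "meioses.tsv", header)

    # --- maps (high-density meioses only) ---------------------------------
    dense = [r for r in records if r.density >= density_threshold]
    logline(f"high-density meioses used for maps: {len(dense)}")
    groups = {}
    for r in dense:
        groups.setdefault((r.breed, r.sex), []).append(r)
    maps = {}
    for (breed, sex), recs in sorted(groups.items()):
        maps[(breed, sex)] = build_recmap(recs, cohort.markers, breed=breed, sex=sex)
        logline(f"map {breed}/{sex}: {len(recs)} meioses, length "
                f"{maps[(breed, sex)].map_length:.2f}")
    if maps:
        write_recmap(list(maps.values()), out / "recombination_maps.tsv")
        corr = pd.DataFrame(
            [[map_correlation(a, b) for b in maps.values()] for a in maps.values()],
            index=[f"{b}_{s}" for b, s in maps], columns=[f"{b}_{s}" for b, s in maps])
        _write(corr, out / "map_correlations.tsv", header, index=True)
        profiles = []
        for (breed, sex), m in maps.items():
            pr = position_profile(m)
            pr.insert(0, "breed", breed)
            pr.insert(1, "sex", sex)
            profiles.append(pr)
        _write(pd.concat(profiles, ignore_index=True),
               out / "position_profiles.tsv", header)

    # --- hotspots ----------------------------------------------------------
    hotspot_sets = {}
    hs_frames = []
    for key, m in maps.items():
        hs = call_hotspots(m, config.hotspot)
        hotspot_sets[key] = hs
        hs_frames.append(hotspots_to_frame(hs, m))
        logline(f"hotspots {key[0]}/{key[1]}: {len(hs)} intervals "
                f"(threshold {hs.threshold:.4g})")
    if hs_frames:
        _write(pd.concat(hs_frames, ignore_index=True),
               out / "hotspots.tsv", header)
    sharing_rows = []
    for sex in config.sexes:
        sets = [hotspot_sets[k] for k in hotspot_sets if k[1] == sex]
        if len(sets) >= 2:
            sh = hotspot_sharing(sets)
            sharing_rows.append({"group": f"breeds_{sex}",
                                 "all_shared": sh["all_shared"],
                                 "union": sh["union"],
                                 **{f"unique_{k}": v for k, v in sh["unique"].items()}})
    if sharing_rows:
        _write(pd.DataFrame(sharing_rows), out / "hotspot_sharing.tsv", header)

    # --- breed comparison ---------------------------------------------------
    scan_frames = []
    for sex in config.sexes:
        breed_groups = {b: recs for (b, s), recs in groups.items() if s == sex}
        for ba, bb in combinations(sorted(breed_groups), 2):
            scan = interval_chisq_scan(breed_groups[ba], breed_groups[bb],
                                       cohort.markers, alpha=config.alpha_compare)
            scan.insert(0, "pair", f"{ba}_vs_{bb}")
            scan.insert(1, "sex", sex)
            scan_frames.append(scan)
            logline(f"compare {ba} vs {bb} ({sex}): "
                    f"{int(scan['significant'].sum())} significant intervals "
                    f"of {int(scan['testable'].sum())} testable")
    if scan_frames:
        _write(pd.concat(scan_frames, ignore_index=True),
               out / "breed_comparison.tsv", header)

    # --- phenotypes + GWAS --------------------------------------------------
    pheno_frames = []
    gwas_frames = []
    for (breed, sex), recs in sorted(groups.items()):
        if len(recs) < 2:
            continue
        traits = {"rate": adjusted_recombination_rate(recs)}
        if (breed, sex) in hotspot_sets:
            traits["usage"] = hotspot_usage(recs, hotspot_sets[(breed, sex)])
        for trait, ph in traits.items():
            labelled = ph.copy()
            labelled.insert(0, "breed", breed)
            labelled.insert(1, "sex", sex)
            labelled.insert(2, "trait", trait)
            pheno_frames.append(labelled)
        for trait, ph in traits.items():
            if len(ph) < 10:
                continue
            model = RecombinationGwas(ph[["animal", "phenotype"]], cohort,
                                      kinship=config.kinship)
            res = model.fit(alpha=config.alpha_gwas)
            t = res.table.copy()
            t.insert(0, "breed", breed)
            t.insert(1, "sex", sex)
            t.insert(2, "trait", trait)
            gwas_frames.append(t)
            logline(f"gwas {breed}/{sex}/{trait}: h2={res.heritability:.3f} "
                    f"[{res.null.flag}], "
                    f"{int(t['significant'].sum())} significant SNPs")
    if pheno_frames:
        _write(pd.concat(pheno_frames, ignore_index=True),
               out / "phenotypes.tsv", header)
    if gwas_frames:
        _write(pd.concat(gwas_frames, ignore_index=True),
               out / "gwas.tsv", header)

    (out / "run.log").write_text(header + "\n".join(log) + "\n")
    return {
        "cohort": cohort,
        "families": fams,
        "records": records,
        "maps": maps,
        "hotspots": hotspot_sets,
        "log": log,
        "outdir": out,
    }
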