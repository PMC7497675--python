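"""Synthetic paired tumour/normal cohorts with planted selection truth.

Generates everything the pipeline consumes — per-patient normal, pre-
and post-therapy VCFs, a variant-to-gene map, damaging-prediction
annotations, a GMT pathway collection and an expression/survival cohort
— from a single seeded configuration, together with a truth record of
every planted feature, so recovery can be scored exactly.

The model: tumours are pure (laser-captured cancer cells), somatic
variants heterozygous, so the mutant allele frequency equals half the
cancer-cell fraction (CCF).  Germline sites are drawn from a shared
cohort pool (common variants recur across patients, so the pooled
normal union exceeds any matched set); heterozygous sites sample reads
at frequency 0.5, homozygous at 1.0.  Read depth is Poisson; alt reads
are binomial at the error-adjusted allele frequency; a site is "called"
only when at least one alt read is observed — which is exactly how a
heterozygous germline variant escapes the normal and leaks into the
somatic set, at rate (1/2)^depth.  Planted drivers shift CCF through
therapy consistently across their carrier patients; passengers drift
with small Gaussian noise.  Damaging annotations are enriched on
drivers (SIFT below 0.05); one planted pathway collects the
direction-A driver genes; planted prognostic genes scale an
exponential survival hazard in the expression cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DriverSpec",
    "SyntheticCohortConfig",
    "TruthRecord",
    "sample_reads",
    "generate_cohort",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class DriverSpec:
    """One planted driver gene: direction, recurrence and CCF shift."""

    gene: str
    direction: str  # "A" (lost/reduced) or "B" (gained/increased)
    recurrence: int  # number of carrier patients
    ccf_pre: float
    ccf_post: float

    def __post_init__(self) -> None:
        if self.direction not in ("A", "B"):
            raise ValueError("driver direction must be A or B")
        if not (0.0 <= self.ccf_pre <= 1.0 and 0.0 <= self.ccf_post <= 1.0):
            raise ValueError("CCFs must lie in [0, 1]")
        if self.direction == "A" and self.ccf_post >= self.ccf_pre:
            raise ValueError(f"direction A driver {self.gene} must lose CCF")
        if self.direction == "B" and self.ccf_post <= self.ccf_pre:
            raise ValueError(f"direction B driver {self.gene} must gain CCF")


def _default_drivers() -> tuple:
    return (
        DriverSpec("DRVA1", "A", 3, 0.6, 0.0),
        DriverSpec("DRVA2", "A", 2, 0.6, 0.0),
        DriverSpec("DRVA3", "A", 3, 0.6, 0.3),
        DriverSpec("DRVA4", "A", 4, 0.7, 0.1),
        DriverSpec("DRVB1", "B", 2, 0.2, 0.8),
        DriverSpec("DRVB2", "B", 3, 0.2, 0.7),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All planted-truth parameters of the generator.

    Defaults are a desk-scale rendition of the study design: six
    patients, recurrent direction-consistent drivers in 2–4 patients,
    passenger drift well below the 5-percentage-point classification
    threshold, and ~30x mean depth (configurable down to 15 to exercise
    the heterozygote-miss risk).
    """

    n_patients: int = 6
    n_genes: int = 2000
    drivers: tuple = field(default_factory=_default_drivers)
    n_het: int = 400
    n_hom: int = 150
    germline_pool_factor: float = 2.0  # pool size / per-patient germline size
    n_passenger: int = 120
    passenger_drift_sd: float = 0.02
    indel_fraction: float = 0.1
    tumour_depth_mean: float = 30.0
    normal_depth_mean: float = 30.0
    error_rate: float = 0.001
    low_qual_fraction: float = 0.02  # decoy calls with QUAL < 30
    pathway_id: str = "PLANTED_ECM"
    pathway_extra_genes: int = 4
    n_decoy_sets: int = 30
    n_survival: int = 300
    n_null_genes: int = 8
    hazard_log_hr: float = float(np.log(2.0))  # per expression z unit
    baseline_hazard: float = 1.0 / 120.0  # events per month
    censor_max: float = 240.0  # months
    tumour_purity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("passenger_drift_sd", "error_rate", "low_qual_fraction",
                     "indel_fraction", "tumour_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for d in self.drivers:
            if d.recurrence > self.n_patients:
                raise ValueError(
                    f"driver {d.gene} recurrence {d.recurrence} exceeds "
                    f"n_patients {self.n_patients}"
                )


@dataclass
class TruthRecord:
    """Ground truth of everything the generator planted."""

    drivers: dict  # gene -> DriverSpec
    driver_patients: dict  # gene -> tuple of patient ids
    driver_variants: dict  # (gene, patient) -> (chrom, pos, ref, alt)
    germline_keys: dict  # patient -> set of (chrom, pos, ref, alt)
    germline_het_keys: dict  # patient -> subset of germline_keys that are heterozygous
    pooled_germline: set
    pathway_id: str
    pathway_members: frozenset
    prognostic_genes: frozenset
    gene_roles: dict  # gene -> driver_A | driver_B | passenger


def sample_reads(true_maf: float, depth_mean: float, error_rate: float, rng) -> tuple[int, int]:
    """Draw (depth, alt_depth) for one site.

    Depth is Poisson(depth_mean) truncated to >= 1; alt reads are
    binomial at the error-adjusted allele frequency
    maf*(1-e) + (1-maf)*e (a wrong base call flips ref to alt or back).
    """
    if not 0.0 <= true_maf <= 1.0:
        raise ValueError("true_maf must lie in [0, 1]")
    depth = int(rng.poisson(depth_mean))
    if depth == 0:
        depth = 1
    p = true_maf * (1.0 - error_rate) + (1.0 - true_maf) * error_rate
    alt = int(rng.binomial(depth, p))
    return depth, alt


# ---------------------------------------------------------------------------
# genome scaffold

def _gene_symbols(cfg: SyntheticCohortConfig) -> list[str]:
    drivers = [d.gene for d in cfg.drivers]
    n_passenger_genes = cfg.n_genes - len(drivers)
    return drivers + [f"GENE{i:04d}" for i in range(n_passenger_genes)]


def _gene_locus(gene_index: int) -> tuple[str, int]:
    chrom = str(gene_index % 22 + 1)
    start = 1_000_000 + (gene_index // 22) * 100_000
    return chrom, start


def _random_site(gene_index: int, rng, used: set) -> tuple[str, int]:
    chrom, start = _gene_locus(gene_index)
    while True:
        pos = start + int(rng.integers(0, 50_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _random_alleles(rng, indel_fraction: float) -> tuple[str, str]:
    r = rng.random()
    ref = _BASES[rng.integers(0, 4)]
    if r < 1.0 - indel_fraction:
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
    elif r < 1.0 - indel_fraction / 2:  # insertion
        alt = ref + "".join(
            _BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4)))
        )
    else:  # deletion
        ref = ref + "".join(
            _BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4)))
        )
        alt = ref[0]
    return ref, alt


# ---------------------------------------------------------------------------
# VCF writing

_VCF_HEADER = """##fileformat=VCFv4.2
##source=chemoselect-synthetic
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def _chrom_order(chrom: str) -> tuple:
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _write_vcf(path: str, sample: str, records: list) -> None:
    """records: (chrom, pos, ref, alt, qual, depth, alt_depth)"""
    contigs = sorted({r[0] for r in records}, key=_chrom_order)
    with open(path, "w", newline="") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for chrom, pos, ref, alt, qual, depth, ad in sorted(
            records, key=lambda r: (_chrom_order(r[0]), r[1], r[3])
        ):
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\tPASS\tDP={depth}\t"
                f"GT:DP:AD\t0/1:{depth}:{depth - ad},{ad}\n"
            )


# ---------------------------------------------------------------------------
# generator

def generate_cohort(cfg: SyntheticCohortConfig, outdir: str) -> TruthRecord:
    """Write the full fixture set into ``outdir`` and return the truth.

    Identical configuration (including seed) produces byte-identical
    files.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(outdir, exist_ok=True)
    genes = _gene_symbols(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    patients = [f"P{i + 1}" for i in range(cfg.n_patients)]
    used_sites: set = set()

    # --- germline pool shared across the cohort (common variants)
    per_patient_germline = cfg.n_het + cfg.n_hom
    pool_size = int(round(cfg.germline_pool_factor * per_patient_germline))
    pool = []
    for _ in range(pool_size):
        gi = int(rng.integers(0, len(genes)))
        chrom, pos = _random_site(gi, rng, used_sites)
        ref, alt = _random_alleles(rng, cfg.indel_fraction)
        pool.append((chrom, pos, ref, alt))
    germline: dict[str, list] = {}
    germline_zygosity: dict[str, list] = {}
    for pid in patients:
        idx = rng.choice(pool_size, size=per_patient_germline, replace=False)
        sites = [pool[i] for i in sorted(idx.tolist())]
        zyg = ["het"] * cfg.n_het + ["hom"] * cfg.n_hom
        rng.shuffle(zyg)
        germline[pid] = sites
        germline_zygosity[pid] = zyg

    # --- somatic truth: passengers then planted drivers
    somatic: dict[str, list] = {pid: [] for pid in patients}
    # entries: (chrom, pos, ref, alt, gene, ccf_pre, ccf_post, role)
    passenger_genes = [g for g in genes if g not in {d.gene for d in cfg.drivers}]
    for pid in patients:
        for _ in range(cfg.n_passenger):
            gene = passenger_genes[int(rng.integers(0, len(passenger_genes)))]
            chrom, pos = _random_site(gene_index[gene], rng, used_sites)
            ref, alt = _random_alleles(rng, cfg.indel_fraction)
            ccf_pre = float(rng.uniform(0.1, 0.9))
            ccf_post = float(
                np.clip(ccf_pre + rng.normal(0.0, cfg.passenger_drift_sd), 0.0, 1.0)
            )
            somatic[pid].append(
                (chrom, pos, ref, alt, gene, ccf_pre, ccf_post, "passenger")
            )
    driver_patients: dict[str, tuple] = {}
    driver_variants: dict[tuple, tuple] = {}
    for d in cfg.drivers:
        carriers = rng.choice(cfg.n_patients, size=d.recurrence, replace=False)
        carrier_ids = tuple(patients[i] for i in sorted(carriers.tolist()))
        driver_patients[d.gene] = carrier_ids
        for pid in carrier_ids:
            chrom, pos = _random_site(gene_index[d.gene], rng, used_sites)
            ref, alt = _random_alleles(rng, cfg.indel_fraction)
            somatic[pid].append(
                (chrom, pos, ref, alt, d.gene, d.ccf_pre, d.ccf_post,
                 f"driver_{d.direction}")
            )
            driver_variants[(d.gene, pid)] = (chrom, pos, ref, alt)

    # --- sample reads and write VCFs
    def qual(rng) -> float:
        if rng.random() < cfg.low_qual_fraction:
            return float(rng.uniform(5.0, 29.0))
        return float(rng.uniform(50.0, 1500.0))

    germline_keys: dict[str, set] = {}
    germline_het_keys: dict[str, set] = {}
    for pid in patients:
        normal_records = []
        pre_records = []
        post_records = []
        gkeys = set()
        hkeys = set()
        for (chrom, pos, ref, alt), zyg in zip(germline[pid], germline_zygosity[pid]):
            gkeys.add((chrom, pos, ref, alt))
            if zyg == "het":
                hkeys.add((chrom, pos, ref, alt))
            maf = 0.5 if zyg == "het" else 1.0
            for records, depth_mean in (
                (normal_records, cfg.normal_depth_mean),
                (pre_records, cfg.tumour_depth_mean),
                (post_records, cfg.tumour_depth_mean),
            ):
                depth, ad = sample_reads(maf, depth_mean, cfg.error_rate, rng)
                if ad >= 1:
                    records.append((chrom, pos, ref, alt, qual(rng), depth, ad))
        for chrom, pos, ref, alt, gene, ccf_pre, ccf_post, _role in somatic[pid]:
            for records, ccf in ((pre_records, ccf_pre), (post_records, ccf_post)):
                maf = cfg.tumour_purity * ccf / 2.0  # heterozygous somatic
                depth, ad = sample_reads(maf, cfg.tumour_depth_mean, cfg.error_rate, rng)
                if ad >= 1:
                    records.append((chrom, pos, ref, alt, qual(rng), depth, ad))
        germline_keys[pid] = gkeys
        germline_het_keys[pid] = hkeys
        _write_vcf(os.path.join(outdir, f"{pid}_normal.vcf"), f"{pid}_normal", normal_records)
        _write_vcf(os.path.join(outdir, f"{pid}_pre.vcf"), f"{pid}_pre", pre_records)
        _write_vcf(os.path.join(outdir, f"{pid}_post.vcf"), f"{pid}_post", post_records)

    # --- gene map (all somatic variants) and damaging annotations
    gene_rows = []
    ann_rows = []
    for pid in patients:
        for chrom, pos, ref, alt, gene, _cp, _cq, role in somatic[pid]:
            gene_rows.append((chrom, pos, ref, alt, gene))
            if role == "passenger":
                sift = float(rng.uniform(0.05, 1.0))
                poly = ["benign", "possibly_damaging", "probably_damaging"][
                    int(rng.choice(3, p=[0.90, 0.07, 0.03]))
                ]
            else:
                sift = float(rng.uniform(0.0, 0.05))
                poly = ["benign", "possibly_damaging", "probably_damaging"][
                    int(rng.choice(3, p=[0.10, 0.20, 0.70]))
                ]
            ann_rows.append((chrom, pos, ref, alt, sift, poly))
    with open(os.path.join(outdir, "gene_map.tsv"), "w", newline="") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\n")
        for row in sorted(set(gene_rows), key=lambda r: (_chrom_order(r[0]), r[1:])):
            fh.write("\t".join(map(str, row)) + "\n")
    with open(os.path.join(outdir, "annotations.tsv"), "w", newline="") as fh:
        fh.write("chrom\tpos\tref\talt\tsift_score\tpolyphen_call\n")
        for chrom, pos, ref, alt, sift, poly in sorted(
            ann_rows, key=lambda r: (_chrom_order(r[0]), r[1], r[2], r[3])
        ):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{sift:.4f}\t{poly}\n")

    # --- pathway collection: one planted set (all driver genes) + decoys
    driver_genes = [d.gene for d in cfg.drivers]
    extra = [
        passenger_genes[int(rng.integers(0, len(passenger_genes)))]
        for _ in range(cfg.pathway_extra_genes)
    ]
    pathway_members = sorted(set(driver_genes + extra))
    with open(os.path.join(outdir, "pathways.gmt"), "w", newline="") as fh:
        fh.write(
            cfg.pathway_id + "\tplanted extracellular-matrix-like pathway\t"
            + "\t".join(pathway_members) + "\n"
        )
        for i in range(cfg.n_decoy_sets):
            size = int(rng.integers(15, 26))
            members = sorted(
                genes[j] for j in rng.choice(len(genes), size=size, replace=False)
            )
            fh.write(f"DECOY{i:03d}\trandom decoy set\t" + "\t".join(members) + "\n")

    # --- expression + survival cohort
    prognostic = sorted(d.gene for d in cfg.drivers)
    null_genes = [f"NULL{i:02d}" for i in range(cfg.n_null_genes)]
    panel = prognostic + null_genes
    z = rng.standard_normal((cfg.n_survival, len(panel)))
    loghaz = np.log(cfg.baseline_hazard) + cfg.hazard_log_hr * z[
        :, : len(prognostic)
    ].sum(axis=1)
    t_event = rng.exponential(1.0 / np.exp(loghaz))
    t_censor = rng.uniform(1.0, cfg.censor_max, size=cfg.n_survival)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    with open(os.path.join(outdir, "survival_cohort.tsv"), "w", newline="") as fh:
        fh.write("patient_id\tsurvival_time\tevent\t" + "\t".join(panel) + "\n")
        for i in range(cfg.n_survival):
            zs = "\t".join(f"{v:.4f}" for v in z[i])
            fh.write(f"M{i:04d}\t{time[i]:.3f}\t{event[i]}\t{zs}\n")

    truth = TruthRecord(
        drivers={d.gene: d for d in cfg.drivers},
        driver_patients=driver_patients,
        driver_variants=driver_variants,
        germline_keys=germline_keys,
        germline_het_keys=germline_het_keys,
        pooled_germline=set().union(*germline_keys.values()),
        pathway_id=cfg.pathway_id,
        pathway_members=frozenset(pathway_members),
        prognostic_genes=frozenset(prognostic),
        gene_roles={
            **{d.gene: f"driver_{d.direction}" for d in cfg.drivers},
            **{g: "passenger" for g in passenger_genes},
        },
    )
    _write_truth_tsv(os.path.join(outdir, "truth.tsv"), truth)
    return truth


def _write_truth_tsv(path: str, truth: TruthRecord) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("record\tgene\tdirection\tpatient\tchrom\tpos\tref\talt\n")
        for gene, spec in sorted(truth.drivers.items()):
            for pid in truth.driver_patients[gene]:
                chrom, pos, ref, alt = truth.driver_variants[(gene, pid)]
                fh.write(
                    f"driver\t{gene}\t{spec.direction}\t{pid}\t{chrom}\t{pos}\t{ref}\t{alt}\n"
                )
        for gene in sorted(truth.pathway_members):
            fh.write(f"pathway\t{gene}\t\t\t\t\t\t\n")
        for gene in sorted(truth.prognostic_genes):
            fh.write(f"prognostic\t{gene}\t\t\t\t\t\t\n")
        for pid in sorted(truth.germline_keys):
            het = truth.germline_het_keys[pid]
            for chrom, pos, ref, alt in sorted(
                truth.germline_keys[pid], key=lambda r: (_chrom_order(r[0]), r[1:])
            ):
                kind = "germline_het" if (chrom, pos, ref, alt) in het else "germline_hom"
                fh.write(f"{kind}\t\t\t{pid}\t{chrom}\t{pos}\t{ref}\t{alt}\n")
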