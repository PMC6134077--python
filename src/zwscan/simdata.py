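"""Forward simulation of ZW fish families segregating a two-locus sex-reversal rule.

The generator emulates the study design under which the downstream analysis
operates: fry from a small number of full-sib families, genotyped at SNPs
spread over 20 autosomes plus the W and Z chromosomes, with two linked causal
loci on Z.  A genetic female (ZW) reverses into a phenotypic male
("pseudomale") exactly when her single Z carries the unfavorable T allele at
the first locus AND she carries at least one unfavorable A allele at the
second locus; ZZ individuals are always phenotypic males and never scored as
reversed.

Transmission genetics implemented literally:

* autosomes: Mendelian, one uniform crossover per chromosome per meiosis;
* the Z has no pairing partner in ZW individuals, so ZW dams transmit an
  intact Z or an intact W with probability 1/2 each, and pseudomale (ZW)
  sires transmit only their intact Z — the T–A haplotype never recombines
  away in a pseudomale lineage;
* ZZ sires recombine their two Z copies like an autosome;
* WW zygotes cannot arise from these crosses (pseudomales pass no W); a
  guard removes them should a custom cross ever produce one.

Z-linked genotypes of ZW individuals are hemizygous and coded on the diploid
scale (0 or 2, never 1); W-linked genotypes of ZZ individuals are missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CHROM_ORDER,
    GenotypeData,
    chrom_sort_key,
    write_genotypes_tsv,
    write_genotypes_vcf,
    write_phenotypes,
)

logger = logging.getLogger(__name__)

#: Default per-chromosome SNP counts of the genotyping panel the generator
#: emulates (scalable via ``marker_scale``).
DEFAULT_MARKER_COUNTS: dict[str, int] = {
    "1": 2961, "2": 1753, "3": 1372, "4": 1597, "5": 1734, "6": 1544,
    "7": 1309, "8": 2395, "9": 1597, "10": 1644, "11": 1612, "12": 1556,
    "13": 1576, "14": 1951, "15": 1503, "16": 1491, "17": 1414, "18": 1236,
    "19": 1345, "20": 1215, "W": 119, "Z": 486,
}

#: Chromosome spans (bp) of the same panel.
DEFAULT_CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 34_507_330, "2": 20_046_420, "3": 16_215_930, "4": 19_961_160,
    "5": 19_261_090, "6": 18_822_360, "7": 13_781_540, "8": 30_122_430,
    "9": 19_598_370, "10": 20_955_540, "11": 20_460_020, "12": 18_351_670,
    "13": 21_859_250, "14": 28_830_960, "15": 20_055_860, "16": 18_775_840,
    "17": 16_457_470, "18": 15_099_100, "19": 17_722_990, "20": 15_203_230,
    "W": 15_839_720, "Z": 21_149_800,
}

NORMAL_ZZ = "normal_ZZ"
PSEUDOMALE_ZW = "pseudomale_ZW"


@dataclass
class SimConfig:
    """Configuration of one simulated population.

    Defaults reproduce the study conditions: 9 families, ~48 offspring each
    (so the Z^T W cohort is ~171 in expectation), the full marker panel
    scaled by ``marker_scale``, two causal Z loci at 6,676,874 and
    8,564,889 bp with unfavorable alleles T and A, and deterministic
    penetrance.
    """

    n_families: int = 9
    n_offspring_per_family: int = 48
    marker_scale: float = 1.0
    marker_counts: dict[str, int] | None = None
    chromosome_lengths_bp: dict[str, int] | None = None
    causal_positions: tuple[int, int] = (6_676_874, 8_564_889)
    unfavorable_alleles: tuple[str, str] = ("T", "A")
    favorable_alleles: tuple[str, str] = ("A", "G")
    causal_t_freq: float = 0.8
    causal_a_freq: float = 0.5
    sire_het_locus2: bool = True
    penetrance_noise: float = 0.0
    missing_rate: float = 0.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    duplication_het_rate: float = 0.0
    sire_types: Sequence[str] | str = NORMAL_ZZ
    seed: int = 0

    def resolved_marker_counts(self) -> dict[str, int]:
        counts = dict(self.marker_counts or {})
        if not counts:
            counts = {
                c: max(2, int(round(n * self.marker_scale)))
                for c, n in DEFAULT_MARKER_COUNTS.items()
            }
        return counts

    def resolved_lengths(self) -> dict[str, int]:
        return dict(self.chromosome_lengths_bp or DEFAULT_CHROM_LENGTHS_BP)

    def resolved_sire_types(self) -> list[str]:
        st = self.sire_types
        if isinstance(st, str):
            types = [st] * self.n_families
        else:
            types = [str(s) for s in st]
            if len(types) != self.n_families:
                raise ValueError("sire_types must have one entry per family")
        bad = set(types) - {NORMAL_ZZ, PSEUDOMALE_ZW}
        if bad:
            raise ValueError(f"unknown sire types {bad}")
        return types

    def validate(self) -> None:
        counts = self.resolved_marker_counts()
        lengths = self.resolved_lengths()
        allowed = set(CHROM_ORDER)
        if not set(counts) <= allowed:
            raise ValueError(f"marker_counts keys outside {{1..20,W,Z}}")
        if counts.get("Z", 0) < 1:
            raise ValueError("Z chromosome needs markers: causal loci are Z-linked")
        z_len = lengths["Z"]
        for p in self.causal_positions:
            if not 1 <= p <= z_len:
                raise ValueError(f"causal position {p} outside Z span (1..{z_len})")
        for name in ("penetrance_noise", "missing_rate", "causal_t_freq",
                     "causal_a_freq", "duplication_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_families < 1 or self.n_offspring_per_family < 1:
            raise ValueError("need at least one family and one offspring")
        self.resolved_sire_types()


def _marker_positions(
    rng: np.random.Generator, counts: Mapping[str, int],
    lengths: Mapping[str, int], causal: tuple[int, int],
) -> dict[str, np.ndarray]:
    """Random unique positions per chromosome; causal positions forced onto Z."""
    pos: dict[str, np.ndarray] = {}
    for chrom in sorted(counts, key=chrom_sort_key):
        n = min(counts[chrom], lengths[chrom])
        length = lengths[chrom]
        p = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
        while p.size < n:  # rare collision top-up
            p = np.unique(
                np.concatenate([p, rng.integers(1, length + 1, size=n)])
            )
        p = np.sort(rng.choice(p, size=n, replace=False))
        if chrom == "Z":
            p = np.unique(np.concatenate([p, np.asarray(causal)]))
        pos[chrom] = p
    return pos


def _gamete(rng: np.random.Generator, haps: np.ndarray, positions: np.ndarray,
            length: int) -> np.ndarray:
    """One recombinant gamete: single uniform crossover between the two haplotypes."""
    start = int(rng.integers(2))
    cx = rng.uniform(0, length)
    return np.where(positions <= cx, haps[start], haps[1 - start])


@dataclass
class _Founder:
    autosomes: dict[str, np.ndarray]  # chrom -> (2, n_markers) alt-allele indicators
    z: np.ndarray                     # (n_z_haps, n_z_markers)
    w: np.ndarray | None              # (n_w_markers,) or None
    genetic_sex: str                  # "ZZ" or "ZW"


def _draw_founder(
    rng: np.random.Generator, freqs: Mapping[str, np.ndarray],
    genetic_sex: str, z_causal_idx: tuple[int, int],
    t_freq: float, a_freq: float, force_ta: bool,
    het_locus2: bool = False,
) -> _Founder:
    autosomes = {}
    for chrom, f in freqs.items():
        if chrom in ("Z", "W"):
            continue
        autosomes[chrom] = (rng.random((2, f.size)) < f).astype(np.int8)
    n_z = 2 if genetic_sex == "ZZ" else 1
    fz = freqs["Z"]
    z = (rng.random((n_z, fz.size)) < fz).astype(np.int8)
    i1, i2 = z_causal_idx
    z[:, i1] = rng.random(n_z) < t_freq
    z[:, i2] = rng.random(n_z) < a_freq
    if het_locus2 and n_z == 2:
        # family segregates for the reversal allele: one A and one G Z copy
        order = int(rng.integers(2))
        z[order, i2] = 1
        z[1 - order, i2] = 0
    if force_ta:  # pseudomale sires must carry the unfavorable T-A haplotype
        z[:, i1] = 1
        z[:, i2] = 1
    w = None
    if genetic_sex == "ZW":
        fw = freqs["W"]
        w = (rng.random(fw.size) < fw).astype(np.int8)
    return _Founder(autosomes, z, w, genetic_sex)


def simulate_population(
    config: SimConfig,
) -> tuple[GenotypeData, pd.DataFrame, pd.DataFrame]:
    """Simulate offspring genotypes, phenotypes and a causal-genotype truth table.

    Returns
    -------
    geno : GenotypeData
        Offspring additive genotypes over every simulated marker.
    pheno : DataFrame
        Columns ``id, sire, dam, genetic_sex, phenotypic_sex, reversal``.
    truth : DataFrame
        Per offspring: the hemizygous/diploid causal genotypes (``g1_allele``
        in {A, T}, ``g2_genotype`` in {GG, AG, AA}) and the noiseless rule
        outcome ``rule_reversal`` so locus-recovery tests have ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.resolved_marker_counts()
    lengths = config.resolved_lengths()
    positions = _marker_positions(rng, counts, lengths, config.causal_positions)
    chroms = sorted(positions, key=chrom_sort_key)

    # founder allele frequencies per marker (alternate allele)
    freqs = {
        c: rng.uniform(config.maf_low, config.maf_high, size=positions[c].size)
        for c in chroms
    }
    z_pos = positions["Z"]
    i1 = int(np.searchsorted(z_pos, config.causal_positions[0]))
    i2 = int(np.searchsorted(z_pos, config.causal_positions[1]))

    sire_types = config.resolved_sire_types()
    records, truth_rows = [], []
    geno_rows: list[np.ndarray] = []
    ids: list[str] = []

    autosome_list = [c for c in chroms if c not in ("Z", "W")]
    for fam in range(config.n_families):
        sire_id, dam_id = f"F{fam+1}_sire", f"F{fam+1}_dam"
        pseudomale = sire_types[fam] == PSEUDOMALE_ZW
        sire = _draw_founder(
            rng, freqs, "ZW" if pseudomale else "ZZ",
            (i1, i2), config.causal_t_freq, config.causal_a_freq, pseudomale,
            het_locus2=config.sire_het_locus2,
        )
        dam = _draw_founder(
            rng, freqs, "ZW", (i1, i2),
            config.causal_t_freq, config.causal_a_freq, False,
        )
        for k in range(config.n_offspring_per_family):
            oid = f"F{fam+1}_O{k+1}"
            # autosomal gametes
            geno_chrom: dict[str, np.ndarray] = {}
            for c in autosome_list:
                gs = _gamete(rng, sire.autosomes[c], positions[c], lengths[c])
                gd = _gamete(rng, dam.autosomes[c], positions[c], lengths[c])
                geno_chrom[c] = (gs + gd).astype(float)
            # sex chromosomes: dam passes intact Z or W; sire passes Z
            if pseudomale:
                sire_z = sire.z[0]  # intact, no synapsis
            else:
                sire_z = _gamete(rng, sire.z, z_pos, lengths["Z"])
            dam_passes_w = bool(rng.random() < 0.5)
            if dam_passes_w:
                genetic_sex = "ZW"
                z_geno = 2.0 * sire_z
                w_geno = 2.0 * dam.w
            else:
                genetic_sex = "ZZ"
                z_geno = (sire_z + dam.z[0]).astype(float)
                w_geno = np.full(positions["W"].size, np.nan)
            geno_chrom["Z"] = z_geno
            geno_chrom["W"] = w_geno

            # causal genotypes + phenotype
            if genetic_sex == "ZW":
                g1 = (config.unfavorable_alleles[0] if sire_z[i1]
                      else config.favorable_alleles[0])
                g2_dose = 2 * int(sire_z[i2])
                if (config.duplication_het_rate > 0
                        and rng.random() < config.duplication_het_rate):
                    g2_dose = 1  # rare heterozygous call: duplicated locus
                    geno_chrom["Z"][i2] = 1.0
                g2 = {0: "GG", 1: "AG", 2: "AA"}[g2_dose]
                rule = int(g1 == config.unfavorable_alleles[0] and "A" in g2)
                reversal = rule
                if config.penetrance_noise > 0 and rng.random() < config.penetrance_noise:
                    reversal = 1 - reversal
                phen_sex = "male" if reversal else "female"
            else:
                g1, g2, rule, reversal = "", "", 0, 0
                phen_sex = "male"

            geno_rows.append(np.concatenate([geno_chrom[c] for c in chroms]))
            ids.append(oid)
            records.append(
                dict(id=oid, sire=sire_id, dam=dam_id, genetic_sex=genetic_sex,
                     phenotypic_sex=phen_sex, reversal=reversal)
            )
            truth_rows.append(
                dict(id=oid, g1_allele=g1, g2_genotype=g2, rule_reversal=rule)
            )

    mm = pd.DataFrame(
        [
            {
                "marker_id": f"Cyn_{c}_{p}",
                "chromosome": c,
                "position_bp": int(p),
                "alleles": _alleles_for(c, int(p), config),
            }
            for c in chroms
            for p in positions[c]
        ]
    )
    geno = GenotypeData(np.vstack(geno_rows), ids, mm)
    if config.missing_rate > 0:
        geno = inject_missingness(
            geno, config.missing_rate, int(rng.integers(2**31))
        )
    pheno = pd.DataFrame(records)
    truth = pd.DataFrame(truth_rows)
    return geno, pheno, truth


def _alleles_for(chrom: str, pos: int, config: SimConfig) -> str:
    if chrom == "Z" and pos == config.causal_positions[0]:
        return f"{config.favorable_alleles[0]}/{config.unfavorable_alleles[0]}"
    if chrom == "Z" and pos == config.causal_positions[1]:
        return f"{config.favorable_alleles[1]}/{config.unfavorable_alleles[1]}"
    return "A/G"


def causal_marker_ids(config: SimConfig) -> tuple[str, str]:
    """Marker ids of the two causal Z loci under the generator's naming scheme."""
    p1, p2 = config.causal_positions
    return f"Cyn_Z_{p1}", f"Cyn_Z_{p2}"


def inject_missingness(
    geno: GenotypeData, rate: float, seed: int
) -> GenotypeData:
    """Replace each observed call by the missing sentinel independently at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0,1), got {rate}")
    rng = np.random.default_rng(seed)
    values = geno.values.copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    return GenotypeData(values, list(geno.individual_ids), geno.marker_map.copy())


def simulate_ztw_cohort(
    n_cohort: int = 171,
    config: SimConfig | None = None,
) -> tuple[GenotypeData, pd.DataFrame, pd.DataFrame]:
    """Simulate a population and keep exactly ``n_cohort`` Z^T W offspring
    (first in family order); family sizes are grown geometrically if the
    first draw yields too few.

    This reproduces the study's sampling: only genetic females carrying the
    unfavorable T allele at the first causal locus enter the genome scan.
    """
    cfg = config or SimConfig()
    unfav1 = cfg.unfavorable_alleles[0]
    for factor in (1, 2, 4, 8, 16):
        bcfg = replace(
            cfg, n_offspring_per_family=cfg.n_offspring_per_family * factor
        )
        geno, pheno, truth = simulate_population(bcfg)
        t_by_id = truth.set_index("id")
        in_cohort = (pheno["genetic_sex"] == "ZW") & (
            t_by_id.loc[pheno["id"], "g1_allele"].to_numpy() == unfav1
        )
        if int(in_cohort.sum()) >= n_cohort:
            break
    else:
        raise RuntimeError(
            f"could not assemble {n_cohort} Z^T W individuals; "
            "check causal_t_freq and family sizes"
        )
    cohort_ids = pheno.loc[in_cohort, "id"].tolist()[:n_cohort]
    geno = geno.select_individuals(cohort_ids)
    pheno = pheno.set_index("id").loc[cohort_ids].reset_index()
    truth = t_by_id.loc[cohort_ids].reset_index()
    return geno, pheno, truth


def write_population(
    geno: GenotypeData,
    pheno: pd.DataFrame,
    out_prefix: str | Path,
    vcf: bool = False,
) -> dict[str, Path]:
    """Write the three-file layout (phenotypes, genotypes, marker map) and
    optionally a VCF; returns the paths written."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": prefix.with_suffix(".pheno.tsv"),
        "genotypes": prefix.with_suffix(".geno.tsv"),
        "markers": prefix.with_suffix(".map.tsv"),
    }
    write_phenotypes(pheno, paths["phenotypes"])
    write_genotypes_tsv(geno, paths["genotypes"], paths["markers"])
    if vcf:
        paths["vcf"] = prefix.with_suffix(".vcf")
        write_genotypes_vcf(geno, paths["vcf"])
    return paths
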