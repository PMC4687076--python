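"""Population-structured genotype simulation with planted ancestry-informative SNPs.

The generator emulates a HapMap-style multi-population genotype panel:

* each SNP has an ancestral minor-allele frequency p drawn uniformly from
  ``maf_range``;
* each ancestral lineage's frequency is drawn from the Balding–Nichols
  model, Beta with mean p and variance F * p * (1 - p), where the
  differentiation F is ``aim_divergence`` for the planted
  ancestry-informative SNPs (AIMs) and ``neutral_divergence`` for the rest;
* admixed populations take the weighted mean of their ancestral lineages'
  frequencies;
* genotypes are Hardy–Weinberg draws, Binomial(2, freq), coded as
  alternate-allele counts; columns are flipped afterwards so the coding
  counts the dataset-wide minor allele (as PLINK --recodeA would);
* calls are set missing completely at random with ``missing_rate``.

An optional "cluster" mode plants AIM frequencies directly near 0.05 or
0.95 per lineage, guaranteeing the strongly clustered
near-fixed/near-absent allele pattern regardless of the Beta draw.

No linkage disequilibrium is simulated: SNPs are independent given the
frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    SampleRecord,
    VariantRecord,
    write_labels_tsv,
    write_ped_map,
)


@dataclass
class PopulationSpec:
    """One population: a label, a size and an ancestry assignment.

    ``ancestry`` is either an integer index naming an ancestral lineage
    (each index is an independent Balding–Nichols draw) or a mapping
    ``{lineage index: weight}`` of admixture proportions summing to 1.
    """

    name: str
    n_samples: int
    ancestry: int | Mapping[int, float] = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"population {self.name!r}: n_samples must be >= 1")
        if isinstance(self.ancestry, Mapping):
            w = np.array(list(self.ancestry.values()), dtype=float)
            if (w < 0).any():
                raise ValueError(f"population {self.name!r}: negative admixture weight")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"population {self.name!r}: admixture weights sum to {w.sum()}, not 1"
                )

    @property
    def lineages(self) -> list[int]:
        if isinstance(self.ancestry, Mapping):
            return [int(k) for k in self.ancestry]
        return [int(self.ancestry)]


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    n_snps: int = 1000
    n_aims: int = 50
    aim_divergence: float = 0.6
    neutral_divergence: float = 0.01
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0
    aim_mode: str = "balding-nichols"  # or "cluster"
    cluster_low: float = 0.05
    cluster_high: float = 0.95

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if not 0 < self.aim_divergence < 1:
            raise ValueError("aim_divergence must be in (0, 1)")
        if not 0 <= self.neutral_divergence < self.aim_divergence:
            raise ValueError("neutral_divergence must be in [0, aim_divergence)")
        if self.n_aims > self.n_snps:
            raise ValueError("n_aims cannot exceed n_snps")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.aim_mode not in ("balding-nichols", "cluster"):
            raise ValueError("aim_mode must be 'balding-nichols' or 'cluster'")

    @property
    def n_lineages(self) -> int:
        return max(l for p in self.populations for l in p.lineages) + 1


@dataclass
class FrequencyDraw:
    """Allele frequencies drawn for one simulation."""

    ancestral_p: np.ndarray  # (n_snps,)
    lineage_freq: np.ndarray  # (n_lineages, n_snps)
    population_freq: np.ndarray  # (n_populations, n_snps)
    aim_mask: np.ndarray  # bool (n_snps,)


@dataclass
class SyntheticDataset:
    """A simulated genotype panel with known truth."""

    genotypes: GenotypeMatrix
    labels: np.ndarray  # population name per sample
    truth_aims: np.ndarray  # bool per SNP
    freq_table: pd.DataFrame  # populations x rsids true minor-allele frequency
    config: SimulationConfig


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Per-lineage frequency draw: Beta with mean p, variance F*p*(1-p)."""
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _draw_frequencies(config: SimulationConfig, rng: np.random.Generator) -> FrequencyDraw:
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    aim_mask = np.zeros(config.n_snps, dtype=bool)
    aim_mask[rng.choice(config.n_snps, size=config.n_aims, replace=False)] = True

    n_lin = config.n_lineages
    lineage = np.empty((n_lin, config.n_snps))
    for l in range(n_lin):
        neutral = _balding_nichols(rng, p, config.neutral_divergence)
        if config.aim_mode == "cluster":
            # Each lineage is assigned the near-absent or near-fixed allele
            # state per AIM, with a little jitter.
            n_aim = config.n_aims
            base = np.where(
                rng.random(n_aim) < 0.5, config.cluster_low, config.cluster_high
            )
            jitter = rng.uniform(-0.03, 0.03, size=n_aim)
            aims = np.clip(base + jitter, 0.01, 0.99)
        else:
            aims = _balding_nichols(rng, p, config.aim_divergence)[aim_mask]
        lineage[l] = neutral
        lineage[l, aim_mask] = aims

    pop_freq = np.empty((len(config.populations), config.n_snps))
    for i, pop in enumerate(config.populations):
        if isinstance(pop.ancestry, Mapping):
            w = np.zeros(n_lin)
            for k, v in pop.ancestry.items():
                w[int(k)] = v
            pop_freq[i] = w @ lineage
        else:
            pop_freq[i] = lineage[int(pop.ancestry)]
    return FrequencyDraw(p, lineage, pop_freq, aim_mask)


def draw_allele_frequencies(config: SimulationConfig) -> FrequencyDraw:
    """Draw the per-population allele frequency table. Deterministic given seed."""
    return _draw_frequencies(config, np.random.default_rng(config.seed))


def simulate_genotypes(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full dataset (frequencies, Hardy–Weinberg genotypes, missingness).

    Deterministic given ``config.seed``; the frequency stage reproduces
    :func:`draw_allele_frequencies` exactly.
    """
    rng = np.random.default_rng(config.seed)
    freqs = _draw_frequencies(config, rng)

    blocks = []
    labels = []
    samples: list[SampleRecord] = []
    for i, pop in enumerate(config.populations):
        g = rng.binomial(2, freqs.population_freq[i], size=(pop.n_samples, config.n_snps))
        blocks.append(g.astype(np.int8))
        labels.extend([pop.name] * pop.n_samples)
        samples.extend(
            SampleRecord(family_id=pop.name, individual_id=f"{pop.name}_{j:04d}")
            for j in range(pop.n_samples)
        )
    values = np.vstack(blocks)
    labels = np.asarray(labels)

    if config.missing_rate > 0:
        miss = rng.random(values.shape) < config.missing_rate
        values[miss] = MISSING

    # Flip columns where the counted allele is not the dataset minor allele,
    # so the coding matches PLINK --recodeA on the whole panel.
    nonmiss = values != MISSING
    alt_count = np.where(nonmiss, values, 0).sum(axis=0)
    n_calls = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_calls > 0, alt_count / (2.0 * n_calls), 0.0)
    flip = alt_freq > 0.5
    values[:, flip] = np.where(nonmiss[:, flip], 2 - values[:, flip], MISSING).astype(np.int8)
    pop_freq = freqs.population_freq.copy()
    pop_freq[:, flip] = 1.0 - pop_freq[:, flip]

    width = len(str(config.n_snps))
    variants = [
        VariantRecord(
            chrom="1",
            rsid=f"snp{j + 1:0{width}d}",
            genetic_distance=0.0,
            bp_position=(j + 1) * 1000,
            alleles=("A", "G"),
        )
        for j in range(config.n_snps)
    ]
    # Minor allele letter fixed to 'A' (alphabetically first), so additive
    # recoding after a PED round trip resolves frequency ties back to 'A'.
    matrix = GenotypeMatrix(samples, variants, values, minor_allele=["A"] * config.n_snps)
    freq_table = pd.DataFrame(
        pop_freq, index=[p.name for p in config.populations], columns=matrix.rsids
    )
    return SyntheticDataset(matrix, labels, freqs.aim_mask, freq_table, config)


def write_dataset(data: SyntheticDataset, prefix: str | Path) -> dict[str, Path]:
    """Write PED/MAP, a sample->population labels TSV and a per-SNP truth TSV."""
    prefix = Path(prefix)
    ped, map_ = write_ped_map(data.genotypes, prefix)
    labels_path = prefix.parent / (prefix.name + ".labels.tsv")
    write_labels_tsv(data.genotypes.sample_ids, list(data.labels), labels_path)
    truth_path = prefix.parent / (prefix.name + ".truth.tsv")
    truth = pd.DataFrame({"rsid": data.genotypes.rsids, "is_aim": data.truth_aims.astype(int)})
    truth = pd.concat(
        [truth, data.freq_table.T.reset_index(drop=True).add_prefix("freq_")], axis=1
    )
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return {"ped": ped, "map": map_, "labels": labels_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# HapMap-like benchmark conditions

#: Published per-group training/test sample sizes of the nine-group HapMap
#: Phase 3 panel (CHB, CHD and JPT combined into one East Asian group).
HAPMAP9_TRAIN_SIZES: dict[str, int] = {
    "ASW": 74,
    "CEU": 140,
    "CHB_CHD_JPT": 305,
    "GIH": 86,
    "LWK": 94,
    "MEX": 73,
    "MKK": 156,
    "TSI": 87,
    "YRI": 173,
}

HAPMAP9_TEST_SIZES: dict[str, int] = {
    "ASW": 13,
    "CEU": 25,
    "CHB_CHD_JPT": 54,
    "GIH": 15,
    "LWK": 16,
    "MEX": 13,
    "MKK": 28,
    "TSI": 15,
    "YRI": 30,
}

#: Ancestry layout for the nine-group panel: seven independent lineages
#: plus admixed ASW (West African / European) and MEX (European /
#: Amerindian / West African); lineage 7 (Amerindian) has no unadmixed
#: population of its own.
_HAPMAP9_ANCESTRY: dict[str, int | dict[int, float]] = {
    "YRI": 0,
    "CEU": 1,
    "CHB_CHD_JPT": 2,
    "GIH": 3,
    "LWK": 4,
    "MKK": 5,
    "TSI": 6,
    "ASW": {0: 0.8, 1: 0.2},
    "MEX": {1: 0.50, 7: 0.45, 0: 0.05},
}


def hapmap_like_populations(
    sizes: Mapping[str, int] | None = None,
) -> list[PopulationSpec]:
    """The nine-group population layout with HapMap-like sizes (training
    sizes by default)."""
    if sizes is None:
        sizes = HAPMAP9_TRAIN_SIZES
    return [
        PopulationSpec(name=g, n_samples=int(n), ancestry=_HAPMAP9_ANCESTRY[g])
        for g, n in sizes.items()
    ]


def benchmark_config(
    n_snps: int = 5000,
    n_aims: int = 300,
    aim_divergence: float = 0.6,
    neutral_divergence: float = 0.01,
    missing_rate: float = 0.002,
    seed: int = 0,
    sizes: Mapping[str, int] | None = None,
) -> SimulationConfig:
    """The standard synthetic benchmark: nine HapMap-like groups, a minority
    of strongly divergent planted AIMs among weakly differentiated neutral
    SNPs, and a small missing-call rate."""
    return SimulationConfig(
        populations=hapmap_like_populations(sizes),
        n_snps=n_snps,
        n_aims=n_aims,
        aim_divergence=aim_divergence,
        neutral_divergence=neutral_divergence,
        missing_rate=missing_rate,
        seed=seed,
    )
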