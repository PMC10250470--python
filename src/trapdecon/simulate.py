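"""Synthetic data generators with known ground truth.

``simulate_translatome_dataset`` emulates the structure of a TRAP-seq
experiment on demyelinated lesions: a handful of replicates per timepoint
(default 3 x {control, 3dpi, 7dpi, 10dpi}), per-sample background-mRNA
contamination, and three planted gene classes —

* *negative markers* (default 6): genes of non-target cell types whose
  expected expression is proportional to the sample's contamination fraction
  ``f_s`` (drawn from a Beta distribution), plus a small constant leak
  representing imperfect cell-type specificity;
* *contaminant-driven genes*: same dependence on ``f_s`` as the markers —
  the apparent signal a contamination filter should remove;
* *condition-responsive (DE) genes*: clean genes whose expected expression is
  shifted by a planted log2 fold change in every lesion timepoint relative to
  the first (reference) condition.

Expected FPKM is perturbed by mean-one log-normal multiplicative noise, and
read counts are drawn Poisson around the FPKM-implied mean given gene length
and library size (log-normal noise already supplies overdispersion; a
negative-binomial option exists in the config). The returned
:class:`SimulationTruth` carries everything needed to score recovery — true
``f_s``, the planted gene classes and fold changes — with no access to
generator internals.

Random streams are split per purpose (structure / contamination / noise /
counts) from one seed, so changing one config field does not reshuffle
unrelated draws. Identical config and seed give bit-identical output.

``simulate_two_channel_volume`` builds a two-channel (myelin/axon) intensity
volume with a planted conditional overlap for testing the colocalization
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, GeneAnnotation, GeneSet
from .imagequant import ChannelVolume

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_translatome_dataset",
    "simulate_two_channel_volume",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic translatome.

    Defaults mirror the emulated study design: 3 replicates in each of four
    conditions (no-lesion control plus 3/7/10 days post-injection), a panel
    of 6 negative markers, and moderate per-sample contamination
    (Beta(2, 5), mean ~0.29).
    """

    n_genes: int = 2000
    n_marker_genes: int = 6
    n_contaminant_genes: int = 100
    n_de_genes: int = 200
    n_samples_per_condition: int = 3
    conditions: tuple[str, ...] = ("control", "3dpi", "7dpi", "10dpi")
    contamination_beta: tuple[float, float] = (2.0, 5.0)
    condition_contamination_weights: tuple[float, ...] | None = (0.5, 1.5, 1.0, 0.75)
    contamination_scale: float = 3.0
    marker_leak: float = 0.05
    noise_sigma: float = 0.2
    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 0.6
    de_log2fc: float = 1.0
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_range: tuple[int, int] = (15_000_000, 25_000_000)
    count_model: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1
    seed: int = 1

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_condition < 1:
            raise ValueError("n_genes and n_samples_per_condition must be positive")
        if min(self.n_marker_genes, self.n_contaminant_genes, self.n_de_genes) < 0:
            raise ValueError("gene-class counts must be nonnegative")
        if self.n_marker_genes + self.n_contaminant_genes + self.n_de_genes > self.n_genes:
            raise ValueError("gene classes exceed n_genes")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be nonempty and unique")
        a, b = self.contamination_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        w = self.condition_contamination_weights
        if w is not None:
            if len(w) != len(self.conditions):
                raise ValueError(
                    "condition_contamination_weights must have one weight per "
                    f"condition ({len(self.conditions)}), got {len(w)}"
                )
            if min(w) < 0:
                raise ValueError("contamination weights must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.contamination_scale < 0 or self.marker_leak < 0:
            raise ValueError("contamination_scale and marker_leak must be nonnegative")
        if self.contamination_scale + self.marker_leak == 0:
            raise ValueError("markers need leak > 0 when contamination_scale is 0")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_size_range")
        if self.count_model not in ("poisson", "nb"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.count_model == "nb" and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    contamination_fraction: pd.Series  # f_s per sample
    marker_genes: list[str]
    contaminant_genes: list[str]
    de_genes: dict[str, float]  # gene -> signed planted log2FC
    clean_genes: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    annotation: GeneAnnotation
    markers: GeneSet
    truth: SimulationTruth
    expected_fpkm: pd.DataFrame  # noise-free planted expectation
    library_sizes: pd.Series  # planted per-sample mapped-read totals


def simulate_translatome_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate counts, annotation, marker panel and ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_contam, rng_noise, rng_counts = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    n_cond = len(config.conditions)
    n_samples = n_cond * config.n_samples_per_condition
    samples = [
        f"{cond}_{i + 1}"
        for cond in config.conditions
        for i in range(config.n_samples_per_condition)
    ]
    cond_of = np.repeat(config.conditions, config.n_samples_per_condition)
    meta = pd.DataFrame(
        {"condition": cond_of, "timepoint": cond_of}, index=pd.Index(samples, name="sample")
    )

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    order = rng_structure.permutation(config.n_genes)
    n_m, n_c, n_d = config.n_marker_genes, config.n_contaminant_genes, config.n_de_genes
    marker_ids = [genes[i] for i in order[:n_m]]
    contam_ids = [genes[i] for i in order[n_m : n_m + n_c]]
    de_ids = [genes[i] for i in order[n_m + n_c : n_m + n_c + n_d]]
    special = set(marker_ids) | set(contam_ids) | set(de_ids)
    clean_ids = [g for g in genes if g not in special]

    baseline = 10.0 ** rng_structure.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, config.n_genes
    )
    lengths = rng_structure.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    lib_sizes = rng_structure.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, n_samples
    )
    de_signs = rng_structure.choice([-1.0, 1.0], size=n_d)

    # per-sample contamination: Beta draw scaled by the condition's weight
    # (background mRNA load tracks lesion state, peaking at demyelination)
    f_s = rng_contam.beta(*config.contamination_beta, size=n_samples)
    if config.condition_contamination_weights is not None:
        weight_of = dict(zip(config.conditions, config.condition_contamination_weights))
        f_s = np.minimum(f_s * np.array([weight_of[c] for c in cond_of]), 1.0)

    # planted (noise-free) expected FPKM
    expected = np.empty((config.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    is_lesion = cond_of != config.conditions[0]
    expected[:] = baseline[:, None]
    lfc_by_gene: dict[str, float] = {}
    for g, sign in zip(de_ids, de_signs):
        lfc = sign * config.de_log2fc
        lfc_by_gene[g] = float(lfc)
        expected[gene_pos[g], is_lesion] *= 2.0 ** lfc
    contam_mult = config.marker_leak + config.contamination_scale * f_s
    for g in marker_ids + contam_ids:
        expected[gene_pos[g], :] = baseline[gene_pos[g]] * contam_mult

    sigma = config.noise_sigma
    if sigma > 0:
        noise = np.exp(
            sigma * rng_noise.normal(size=expected.shape) - 0.5 * sigma**2
        )
    else:
        noise = 1.0
    fpkm = expected * noise

    mu = fpkm * lengths[:, None] * lib_sizes[None, :] / 1e9
    if config.count_model == "poisson":
        counts = rng_counts.poisson(mu)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng_counts.gamma(shape, mu * config.nb_dispersion)
        counts = rng_counts.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    annot = GeneAnnotation(lengths=pd.Series(lengths.astype(float), index=genes))
    markers = GeneSet(
        name="negative_markers",
        description="synthetic non-astrocyte cell-type markers",
        members=tuple(marker_ids),
        role="contamination_marker",
    )
    truth = SimulationTruth(
        contamination_fraction=pd.Series(f_s, index=samples, name="f"),
        marker_genes=marker_ids,
        contaminant_genes=contam_ids,
        de_genes=lfc_by_gene,
        clean_genes=clean_ids,
    )
    return SimulatedDataset(
        counts=CountMatrix(counts_df, sample_meta=meta),
        annotation=annot,
        markers=markers,
        truth=truth,
        expected_fpkm=pd.DataFrame(expected, index=counts_df.index, columns=samples),
        library_sizes=pd.Series(lib_sizes, index=samples, name="library_size"),
    )


def simulate_two_channel_volume(
    shape=(128, 128, 128),
    axon_density: float = 0.1,
    overlap: float = 0.4,
    noise_sd: float = 5.0,
    seed: int = 0,
    false_positive_rate: float = 0.005,
    low: float = 30.0,
    high: float = 200.0,
):
    """Two-channel volume with planted conditional overlap.

    Axon voxels are drawn Bernoulli(``axon_density``); a myelin voxel is
    positive on an axon voxel with probability ``overlap`` and off-axon with
    probability ``false_positive_rate``. Intensities sit at two well-separated
    levels (``low``/``high``) plus Gaussian noise of ``noise_sd``.

    Returns ``(myelin, axon, truth)`` where truth records the planted and the
    realized conditional overlap.
    """
    if not (0 < axon_density < 1):
        raise ValueError("axon_density must be in (0, 1)")
    if not (0 <= overlap <= 1):
        raise ValueError("overlap must be in [0, 1]")
    if noise_sd < 0 or not (0 <= false_positive_rate < 1):
        raise ValueError("invalid noise_sd or false_positive_rate")
    rng = np.random.default_rng(seed)
    axon_mask = rng.random(shape) < axon_density
    myelin_mask = np.where(
        axon_mask,
        rng.random(shape) < overlap,
        rng.random(shape) < false_positive_rate,
    )
    def intensify(mask):
        base = np.where(mask, high, low).astype(float)
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, shape)
        return np.clip(base, 0.0, None)

    myelin = ChannelVolume(intensify(myelin_mask), label="MBP")
    axon = ChannelVolume(intensify(axon_mask), label="NFH")
    n_axon = int(axon_mask.sum())
    truth = {
        "planted_overlap": float(overlap),
        "realized_overlap": float((myelin_mask & axon_mask).sum() / n_axon)
        if n_axon
        else float("nan"),
        "axon_voxels": n_axon,
    }
    return myelin, axon, truth
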