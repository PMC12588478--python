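"""Synthetic expression datasets with planted, recoverable structure.

The generator emulates the statistical features the analysis pipeline relies
on in a case/control microarray cohort: block-correlated gene modules drawn
from shared latent factors, class-dependent mean shifts confined to a subset
of genes inside designated "discriminative" modules, per-(batch, gene)
location--scale batch effects on the log scale, and a planted annotation gene
set overlapping one module (a stand-in for a curated disease-gene list).
Everything is deterministic given the seed, and the planted structure is
returned as an explicit ground truth so downstream stages can be scored
against it.

Construction of a module gene: ``x = sqrt(rho) * F_m + sqrt(1 - rho) * eps``
with ``F_m`` the module's latent factor and ``eps`` i.i.d. standard normal,
so every within-module gene pair has correlation exactly ``rho`` in
expectation and unit marginal variance.  The class signal is a mean shift of
``effect_size`` (in units of the unit per-gene SD) added to case samples of
the informative genes only — informative and uninformative genes of one
module therefore share the factor but differ in class signal, which is what
makes in-community feature selection meaningful.  Values are exponentiated to
a microarray-like intensity scale (``2**(x + 8)``) before being returned, so
the preprocessing log2 step operates on realistic input.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from coexcom.io import write_expression, write_metadata

LOG_INTENSITY_CENTER = 8.0  # typical log2 microarray intensity midpoint


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of one synthetic case/control expression dataset.

    Defaults mirror a desk-scale version of a post-mortem brain microarray
    cohort: 104 samples with a 33/71 case/control imbalance, six planted
    modules of 20 genes in a 300-gene matrix, strong within-module
    correlation, two discriminative modules carrying an effect of two
    per-gene SDs on half of their genes, and two processing batches.
    """

    n_genes: int = 300
    n_samples: int = 104
    n_case: int = 33
    module_sizes: tuple = (20, 20, 20, 20, 20, 20)
    within_module_correlation: float = 0.8
    discriminative_modules: tuple = (0, 1)
    effect_size: float = 2.0
    informative_fraction: float = 0.5
    n_batches: int = 2
    batch_shift_sd: float = 0.0
    batch_scale_sd: float = 0.0
    annotation_overlap: int = 6
    annotation_size: int = 10
    annotation_module: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not (0 < self.n_case < self.n_samples):
            raise ValueError("n_case must satisfy 0 < n_case < n_samples")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module_sizes entries must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if not (0 < self.within_module_correlation < 1):
            raise ValueError("within_module_correlation must lie in (0, 1)")
        if any(m < 0 or m >= len(self.module_sizes) for m in self.discriminative_modules):
            raise ValueError("discriminative_modules contains an unknown module index")
        if not (0 < self.informative_fraction <= 1):
            raise ValueError("informative_fraction must lie in (0, 1]")
        if self.n_batches <= 0:
            raise ValueError("n_batches must be positive")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch_shift_sd and batch_scale_sd must be nonnegative")
        if self.annotation_overlap > self.annotation_size:
            raise ValueError("annotation_overlap exceeds annotation_size")
        if self.annotation_module < 0 or self.annotation_module >= len(self.module_sizes):
            raise ValueError("annotation_module is not a valid module index")
        if self.annotation_overlap > self.module_sizes[self.annotation_module]:
            raise ValueError("annotation_overlap exceeds the designated module size")
        if self.annotation_size - self.annotation_overlap > self.n_genes - sum(self.module_sizes):
            raise ValueError("annotation_size requires more background genes than available")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a generated dataset, keyed by gene/sample ids."""

    module_of_gene: dict
    informative_genes: list
    discriminative_modules: list
    batch_of_sample: dict
    class_of_sample: dict
    annotation_set: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def module_genes(self, module: int) -> list:
        return [g for g, m in self.module_of_gene.items() if m == module]


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(n)]


def generate_dataset(config: SyntheticConfig):
    """Generate one dataset; returns (expression, metadata, ground truth).

    The expression matrix is on the intensity scale (genes x samples); the
    metadata frame has columns ``class`` and ``batch`` indexed by sample id.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config.n_genes)
    samples = _sample_ids(config.n_samples)
    classes = np.array(["case"] * config.n_case + ["control"] * (config.n_samples - config.n_case))
    # round-robin within each class so every batch holds both classes
    batch_idx = np.empty(config.n_samples, dtype=int)
    for cls in ("case", "control"):
        members = np.flatnonzero(classes == cls)
        batch_idx[members] = np.arange(members.size) % config.n_batches

    rho = config.within_module_correlation
    log_expr = np.empty((config.n_genes, config.n_samples))
    module_of_gene: dict = {}
    informative: list = []

    gene_pos = 0
    for m, size in enumerate(config.module_sizes):
        factor = rng.standard_normal(config.n_samples)
        noise = rng.standard_normal((size, config.n_samples))
        block = math.sqrt(rho) * factor + math.sqrt(1.0 - rho) * noise
        if m in config.discriminative_modules and config.effect_size != 0:
            n_inf = max(1, math.ceil(config.informative_fraction * size))
            block[:n_inf, classes == "case"] += config.effect_size
            informative.extend(genes[gene_pos + i] for i in range(n_inf))
        elif m in config.discriminative_modules:
            n_inf = max(1, math.ceil(config.informative_fraction * size))
            informative.extend(genes[gene_pos + i] for i in range(n_inf))
        for i in range(size):
            module_of_gene[genes[gene_pos + i]] = m
        log_expr[gene_pos:gene_pos + size] = block
        gene_pos += size
    # background genes: independent unit-variance noise
    n_background = config.n_genes - gene_pos
    log_expr[gene_pos:] = rng.standard_normal((n_background, config.n_samples))

    # per-(batch, gene) location-scale effects on the log scale
    if config.n_batches > 1 and (config.batch_shift_sd > 0 or config.batch_scale_sd > 0):
        shifts = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes))
        log_scales = rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, config.n_genes))
        for b in range(config.n_batches):
            cols = batch_idx == b
            log_expr[:, cols] = (np.exp(log_scales[b])[:, None] * log_expr[:, cols]
                                 + shifts[b][:, None])

    # planted annotation: overlap genes from the designated module, rest from background
    module_members = [g for g in genes[:gene_pos]
                      if module_of_gene[g] == config.annotation_module]
    annotation = list(module_members[:config.annotation_overlap])
    background_genes = genes[gene_pos:]
    annotation.extend(background_genes[:config.annotation_size - config.annotation_overlap])

    intensities = np.exp2(log_expr + LOG_INTENSITY_CENTER)
    matrix = pd.DataFrame(intensities, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    metadata = pd.DataFrame(
        {"class": classes, "batch": [f"batch{b}" for b in batch_idx]},
        index=pd.Index(samples, name="sample_id"),
    )
    truth = GroundTruth(
        module_of_gene=module_of_gene,
        informative_genes=informative,
        discriminative_modules=list(config.discriminative_modules),
        batch_of_sample={s: f"batch{b}" for s, b in zip(samples, batch_idx)},
        class_of_sample=dict(zip(samples, classes.tolist())),
        annotation_set=annotation,
    )
    return matrix, metadata, truth


def generate_hierarchical_dataset(n_super: int = 2, subblocks_per_super: int = 5,
                                  subblock_size: int = 30,
                                  rho_super: float = 0.3, rho_sub: float = 0.7,
                                  n_samples: int = 100, n_case: int = 40,
                                  seed: int = 0):
    """Two-level planted hierarchy for testing recursive detection.

    Each super-block shares a weak latent factor (pairwise correlation
    ``rho_super`` between genes of different sub-blocks); genes within one
    sub-block additionally share a stronger factor so their pairwise
    correlation is ``rho_sub``.  Returns (intensity matrix, metadata,
    {gene: super index}, {gene: global sub-block index}).
    """
    if not (0 < rho_super < rho_sub < 1):
        raise ValueError("need 0 < rho_super < rho_sub < 1")
    rng = np.random.default_rng(seed)
    n_genes = n_super * subblocks_per_super * subblock_size
    genes = _gene_ids(n_genes)
    samples = _sample_ids(n_samples)
    classes = np.array(["case"] * n_case + ["control"] * (n_samples - n_case))

    log_expr = np.empty((n_genes, n_samples))
    super_of, sub_of = {}, {}
    pos = 0
    for s in range(n_super):
        f_super = rng.standard_normal(n_samples)
        for b in range(subblocks_per_super):
            f_sub = rng.standard_normal(n_samples)
            noise = rng.standard_normal((subblock_size, n_samples))
            block = (math.sqrt(rho_super) * f_super
                     + math.sqrt(rho_sub - rho_super) * f_sub
                     + math.sqrt(1.0 - rho_sub) * noise)
            log_expr[pos:pos + subblock_size] = block
            for i in range(subblock_size):
                super_of[genes[pos + i]] = s
                sub_of[genes[pos + i]] = s * subblocks_per_super + b
            pos += subblock_size

    matrix = pd.DataFrame(np.exp2(log_expr + LOG_INTENSITY_CENTER),
                          index=pd.Index(genes, name="gene_id"), columns=samples)
    metadata = pd.DataFrame(
        {"class": classes, "batch": ["batch0"] * n_samples},
        index=pd.Index(samples, name="sample_id"))
    return matrix, metadata, super_of, sub_of


def write_dataset(matrix, metadata, truth: GroundTruth, directory,
                  annotation_name: str = "planted_annotation"):
    """Write expression TSV, metadata TSV, ground-truth JSON and annotation GMT.

    Returns a dict of the written paths.
    """
    if list(matrix.columns) != list(metadata.index):
        raise ValueError("matrix sample ids and metadata rows do not match")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "metadata": directory / "metadata.tsv",
        "ground_truth": directory / "ground_truth.json",
        "annotation": directory / "annotation.gmt",
    }
    write_expression(matrix, paths["expression"])
    write_metadata(metadata, paths["metadata"])
    paths["ground_truth"].write_text(truth.to_json())
    gmt_line = "\t".join([annotation_name, "planted synthetic annotation set",
                          *truth.annotation_set])
    paths["annotation"].write_text(gmt_line + "\n")
    return paths
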