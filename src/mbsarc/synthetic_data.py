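"""Synthetic expression and qPCR data with the structure the classifier assumes.

The generator emulates a four-subgroup bulk expression study: each subgroup
carries a small block of marker genes whose mean is shifted in that subgroup
only, on top of a sea of exchangeable noise genes. Log-scale microarray
intensities after RMA normalization are approximately Gaussian, so cells are
drawn as ``Normal(mean, noise_sd**2)`` with

* noise genes:  mean = ``baseline_mean`` in every sample,
* marker genes: mean = ``baseline_mean + effect_size * noise_sd`` in samples
  of their own subgroup (minus the shift for a configurable "down" fraction
  of markers) and ``baseline_mean`` elsewhere.

Class imbalance is expressed directly through ``n_per_class`` so that the
70/223/144/326 ratio of a large medulloblastoma training cohort can be
mimicked. Generation is a pure function of the config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import CLASS_ORDER, CtTable, ExpressionMatrix, SubgroupLabels

__all__ = ["SimulationConfig", "simulate_expression", "simulate_ct"]

#: n_per_class mirroring the subgroup ratio of the large public training
#: cohort, scaled down one order of magnitude so the default simulation runs
#: in seconds (70/223/144/326 -> 7/22/14/33).
DEFAULT_N_PER_CLASS: dict[str, int] = {"WNT": 7, "SHH": 22, "Group3": 14, "Group4": 33}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic four-subgroup expression study.

    ``effect_size`` is the marker mean shift in units of ``noise_sd``;
    ``baseline_mean`` plays the role of a typical log2 RMA intensity.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_CLASS)
    )
    n_noise_genes: int = 2000
    markers_per_class: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    seed: int = 0
    marker_down_fraction: float = 0.0  # fraction of markers shifted down instead of up

    def __post_init__(self) -> None:
        unknown = [c for c in self.n_per_class if c not in CLASS_ORDER]
        if unknown:
            raise ValueError(f"unknown class name(s) in n_per_class: {unknown}")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("n_per_class counts must be >= 0")
        if sum(n > 0 for n in self.n_per_class.values()) < 2:
            raise ValueError("at least 2 classes must have samples")
        if self.n_noise_genes < 0 or self.markers_per_class < 0:
            raise ValueError("gene counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.marker_down_fraction <= 1.0:
            raise ValueError("marker_down_fraction must be in [0, 1]")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for c in CLASS_ORDER if self.n_per_class.get(c, 0) > 0)


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SubgroupLabels, dict[str, list[str]]]:
    """Draw an expression matrix, its labels, and the planted-marker truth.

    Returns ``(matrix, labels, truth)`` where ``truth`` maps each class to
    the IDs of its marker genes. Row order: all marker blocks (class order,
    then marker index), then noise genes. Column order: samples grouped by
    class in canonical order.
    """
    classes = cfg.classes
    rng = np.random.default_rng(cfg.seed)

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for cls in classes:
        for i in range(cfg.n_per_class[cls]):
            sid = f"{cls}_s{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = cls

    marker_ids: list[str] = []
    truth: dict[str, list[str]] = {c: [] for c in classes}
    for cls in classes:
        for i in range(cfg.markers_per_class):
            gid = f"MK_{cls}_{i + 1:02d}"
            marker_ids.append(gid)
            truth[cls].append(gid)
    noise_ids = [f"NOISE_{i + 1:05d}" for i in range(cfg.n_noise_genes)]
    gene_ids = marker_ids + noise_ids

    n_genes, n_samples = len(gene_ids), len(sample_ids)
    values = rng.normal(cfg.baseline_mean, cfg.noise_sd, size=(n_genes, n_samples))

    shift = cfg.effect_size * cfg.noise_sd
    sample_class = np.array([labels[s] for s in sample_ids])
    row = 0
    for cls in classes:
        in_class = sample_class == cls
        for i in range(cfg.markers_per_class):
            sign = -1.0 if rng.random() < cfg.marker_down_fraction else 1.0
            values[row, in_class] += sign * shift
            row += 1

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    return matrix, SubgroupLabels(labels), truth


def simulate_ct(
    n_per_class: Mapping[str, int],
    markers: Mapping[str, Sequence[str]],
    delta: float = 5.0,
    sd: float = 0.2,
    seed: int = 0,
    *,
    baseline_ct: float = 30.0,
    reference_gene: str = "GAPDH",
    reference_ct: float = 20.0,
    max_cycles: float = 40.0,
) -> tuple[CtTable, SubgroupLabels]:
    """Draw a qPCR Ct table emulating a small clinical validation cohort.

    Each class's marker genes amplify ``delta`` cycles *earlier* (lower Ct =
    higher expression) in samples of that class; all other wells sit at
    ``baseline_ct``. Gaussian well-to-well noise with standard deviation
    ``sd`` is added to every measured gene; the reference gene is constant at
    ``reference_ct`` across samples, so dCt inherits the same structure.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if not markers:
        raise ValueError("marker map must not be empty")
    classes = [c for c in CLASS_ORDER if n_per_class.get(c, 0) > 0]
    if len(classes) < 2:
        raise ValueError("at least 2 classes must have samples")
    unknown = [c for c in markers if c not in CLASS_ORDER]
    if unknown:
        raise ValueError(f"unknown class name(s) in markers: {unknown}")

    gene_ids: list[str] = []
    for cls in CLASS_ORDER:
        for g in markers.get(cls, ()):  # class order keeps gene order stable
            if g not in gene_ids:
                gene_ids.append(g)
    if reference_gene in gene_ids:
        raise ValueError(f"reference gene {reference_gene!r} collides with a marker")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    for cls in classes:
        for i in range(n_per_class[cls]):
            sid = f"{cls}_p{i + 1:02d}"
            sample_ids.append(sid)
            labels[sid] = cls

    ct = np.full((len(gene_ids), len(sample_ids)), baseline_ct, dtype=float)
    for j, sid in enumerate(sample_ids):
        for g in markers.get(labels[sid], ()):  # markers of the sample's class
            ct[gene_ids.index(g), j] -= delta
    ct += rng.normal(0.0, sd, size=ct.shape)
    np.clip(ct, 0.0, max_cycles, out=ct)

    df = pd.DataFrame(ct, index=gene_ids, columns=sample_ids)
    df.loc[reference_gene] = reference_ct
    table = CtTable(df, reference_gene=reference_gene, max_cycles=max_cycles)
    return table, SubgroupLabels(labels)
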