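"""Synthetic MSAP, qPCR and morphometric data with known ground truth.

The MSAP generator draws, for every sample, a methylation type (I-IV) per
locus from its group's per-locus state-probability vector, maps the type
to the two-enzyme band pattern, then corrupts each band call independently
with flip errors and missingness — mirroring how scoring error enters real
fragment data band by band.  A configurable fraction of loci is
differentiated between groups: for those loci, probability mass is moved
from Type I toward Types II/III/IV (proportionally to their baseline
share) in non-reference groups, with the shift growing linearly across
group index so every non-reference group is distinct.  One simulated
sample stands for one biological replicate, whether that replicate is a
pooled batch of larvae or an individual fish.

The qPCR generator produces long-format Cq tables where treatment-group
targets are shifted down by their true log2 fold change (one cycle per
doubling) plus Gaussian cycle noise; reference genes are held at fold
change zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MsapDataset
from .methylation import TYPE_TO_PRESENCE
from .qpcr import QpcrExperiment

#: default Dirichlet concentration for per-locus baseline state probabilities;
#: favours unmethylated (Type I) loci, with II/III/IV present at lower,
#: comparable rates — the shape typical of MSAP band-type tallies.
DEFAULT_DIRICHLET = (6.0, 2.0, 2.0, 2.0)


@dataclass
class MsapSimConfig:
    """Ground-truth structure of a simulated MSAP experiment.

    ``baseline_state_probs`` may be a single 4-vector (shared by all
    loci), an (n_loci, 4) array, or None to draw per-locus vectors from
    Dirichlet(:data:`DEFAULT_DIRICHLET`).
    """

    group_sizes: list[int] = field(default_factory=lambda: [23, 15, 12])
    n_loci: int = 250
    baseline_state_probs: object | None = None
    diff_fraction: float = 0.2
    effect_size: float = 0.3
    error_rate: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def validate(self) -> None:
        if self.n_groups < 1 or any(int(s) != s or s < 1 for s in self.group_sizes):
            raise ConfigurationError("group_sizes must be positive integers")
        if sum(self.group_sizes) < 2:
            raise ConfigurationError("group_sizes must sum to >= 2")
        if int(self.n_loci) != self.n_loci or self.n_loci < 1:
            raise ConfigurationError("n_loci must be a positive integer")
        for name in ("diff_fraction", "effect_size", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_state_probs is not None:
            probs = np.asarray(self.baseline_state_probs, dtype=float)
            if probs.ndim == 1:
                probs = probs[None, :]
            if probs.shape[-1] != 4 or np.any(probs < 0):
                raise ConfigurationError(
                    "baseline_state_probs must be non-negative 4-vectors")
            if np.any(np.abs(probs.sum(axis=-1) - 1) > 1e-12):
                raise ConfigurationError("baseline_state_probs rows must sum to 1")


@dataclass
class QpcrSimConfig:
    """Ground-truth structure of a simulated qPCR experiment.

    ``true_log2fc`` maps gene -> log2 fold change of each non-control
    group relative to the first group in ``groups``; reference genes are
    forced to 0.  ``base_cq`` and ``efficiencies`` map gene -> baseline
    quantification cycle and amplification efficiency.
    """

    genes: list[str] = field(default_factory=lambda: ["dnmt1", "dnmt3", "ef1a", "fau"])
    reference_genes: list[str] = field(default_factory=lambda: ["ef1a", "fau"])
    groups: list[str] = field(default_factory=lambda: ["control", "treatment"])
    n_replicates: int = 4
    true_log2fc: dict[str, float] = field(default_factory=dict)
    base_cq: dict[str, float] | float = 24.0
    efficiencies: dict[str, float] | float = 1.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if len(self.reference_genes) != 2:
            raise ConfigurationError("exactly 2 reference_genes are required")
        for rg in self.reference_genes:
            if rg not in self.genes:
                raise ConfigurationError(f"reference gene {rg!r} not in genes")
            if self.true_log2fc.get(rg, 0.0) != 0.0:
                raise ConfigurationError(
                    f"reference gene {rg!r} must have true_log2fc 0")
        if len(self.groups) < 2:
            raise ConfigurationError("need >= 2 groups")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        effs = self._per_gene(self.efficiencies)
        if any(not 0 < e <= 1 for e in effs.values()):
            raise ConfigurationError("efficiencies must lie in (0, 1]")

    def _per_gene(self, value) -> dict[str, float]:
        if isinstance(value, dict):
            return {g: float(value.get(g, 1.0)) for g in self.genes}
        return {g: float(value) for g in self.genes}


@dataclass
class SimTruth:
    """What the generator knows that the analysis must recover."""

    differentiated_locus_ids: set[str] = field(default_factory=set)
    state_probs: dict[str, np.ndarray] = field(default_factory=dict)  # group -> loci x 4
    true_log2fc: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in sorted(self.differentiated_locus_ids):
            rows.append({"kind": "differentiated_locus", "id": locus, "value": ""})
        for gene, fc in sorted(self.true_log2fc.items()):
            rows.append({"kind": "true_log2fc", "id": gene, "value": repr(fc)})
        return pd.DataFrame(rows, columns=["kind", "id", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _shift_probs(base: np.ndarray, shift: float) -> np.ndarray:
    """Move ``shift`` total-variation mass from Type I to Types II-IV,
    proportionally to their baseline share (uniformly when all are 0)."""
    out = base.copy()
    move = np.minimum(out[:, 0], shift)
    rest = out[:, 1:]
    rest_tot = rest.sum(axis=1, keepdims=True)
    weights = np.where(rest_tot > 0, rest / np.where(rest_tot > 0, rest_tot, 1.0),
                       1.0 / 3.0)
    out[:, 0] -= move
    out[:, 1:] += move[:, None] * weights
    return out


def simulate_msap(config: MsapSimConfig) -> tuple[MsapDataset, SimTruth]:
    """Simulate an MSAP band-presence dataset with known differentiation.

    Deterministic function of ``config.seed``; see the module docstring
    for the generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = int(config.n_loci)
    G = config.n_groups
    if config.baseline_state_probs is None:
        base = rng.dirichlet(DEFAULT_DIRICHLET, size=L)
    else:
        base = np.asarray(config.baseline_state_probs, dtype=float)
        if base.ndim == 1:
            base = np.tile(base, (L, 1))
    locus_ids = [f"L{i + 1:04d}" for i in range(L)]
    n_diff = round(config.diff_fraction * L)
    diff_idx = np.sort(rng.choice(L, size=n_diff, replace=False))
    diff_set = {locus_ids[i] for i in diff_idx}

    group_names = [f"G{g + 1}" for g in range(G)]
    probs_by_group: dict[str, np.ndarray] = {}
    for g in range(G):
        probs = base.copy()
        if g > 0 and n_diff > 0 and G > 1:
            shift = config.effect_size * g / (G - 1)
            probs[diff_idx] = _shift_probs(base[diff_idx], shift)
        probs_by_group[group_names[g]] = probs

    sample_ids: list[str] = []
    group_labels: list[str] = []
    hpa_rows, msp_rows = [], []
    pat = np.array([TYPE_TO_PRESENCE[k] for k in (1, 2, 3, 4)], dtype=float)
    for g, n_g in enumerate(config.group_sizes):
        probs = probs_by_group[group_names[g]]
        cum = np.cumsum(probs, axis=1)
        for r in range(int(n_g)):
            sid = f"{group_names[g]}_S{r + 1:03d}"
            sample_ids.append(sid)
            group_labels.append(group_names[g])
            u = rng.random(L)
            states = (u[:, None] > cum).sum(axis=1)  # 0..3 index into types I..IV
            h = pat[states, 0]
            m = pat[states, 1]
            if config.error_rate > 0:
                h = np.abs(h - (rng.random(L) < config.error_rate))
                m = np.abs(m - (rng.random(L) < config.error_rate))
            if config.missing_rate > 0:
                h[rng.random(L) < config.missing_rate] = np.nan
                m[rng.random(L) < config.missing_rate] = np.nan
            hpa_rows.append(h)
            msp_rows.append(m)
    dataset = MsapDataset(
        sample_ids=sample_ids,
        group_labels=group_labels,
        locus_ids=locus_ids,
        presence_hpa=pd.DataFrame(np.array(hpa_rows), index=sample_ids,
                                  columns=locus_ids),
        presence_msp=pd.DataFrame(np.array(msp_rows), index=sample_ids,
                                  columns=locus_ids),
    )
    truth = SimTruth(
        differentiated_locus_ids=diff_set,
        state_probs=probs_by_group,
    )
    return dataset, truth


def simulate_qpcr(config: QpcrSimConfig) -> tuple[QpcrExperiment, SimTruth]:
    """Simulate a long-format qPCR Cq table.

    Cq = base_cq(gene) - true_log2fc(gene) [treatment groups only]
    + N(0, noise_sd) per replicate; efficiencies are attached per gene.
    Deterministic function of ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_cq = config._per_gene(config.base_cq)
    effs = config._per_gene(config.efficiencies)
    fc = {g: float(config.true_log2fc.get(g, 0.0)) for g in config.genes}
    for rg in config.reference_genes:
        fc[rg] = 0.0
    control = config.groups[0]
    rows = []
    for group in config.groups:
        for r in range(int(config.n_replicates)):
            sid = f"{group}_R{r + 1}"
            for gene in config.genes:
                mu = base_cq[gene]
                if group != control:
                    mu -= fc[gene]
                cq = mu + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
                rows.append({"sample": sid, "group": group, "gene": gene,
                             "cq": cq, "efficiency": effs[gene]})
    experiment = QpcrExperiment(pd.DataFrame(rows),
                                tuple(config.reference_genes))
    refs = set(config.reference_genes)
    truth = SimTruth(true_log2fc={g: fc[g] for g in config.genes if g not in refs})
    return experiment, truth
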