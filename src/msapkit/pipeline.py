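"""End-to-end orchestration of the MSAP and qPCR analyses.

A single :class:`RunConfig` names the inputs, the comparisons (each a set
of group labels analysed together, classified independently — locus sets
therefore differ between comparisons by design), the thresholds and the
seed.  :func:`run_msap_analysis` writes, per comparison: the locus
classification summary, the AMOVA table (overall and pairwise), PCoA
coordinates, the per-locus Fisher/FDR table, the significant-locus
heatmap matrix (Type I-IV codes), the UPGMA tree of significant loci
(Newick), per-sample global methylation ratios and per-group band-type
counts, plus a run log recording seed, thresholds and version.

All table output is tab-separated UTF-8 with LF endings and repr-exact
floats, so identical configs and seeds give byte-identical files.  Every
random stage derives its own stream from the single config seed and the
comparison's position, in a fixed documented order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import MsapDataset, read_band_matrix
from .methylation import (band_type_frequencies, call_methylation_types,
                          classify_loci, global_methylation_ratio)
from .differentiation import amova, pairwise_distances, pairwise_group_amova, pcoa
from .locus_stats import gower_distance, locus_fisher_tests, upgma_cluster
from .qpcr import QpcrExperiment, delta_cq, expression_tests, summaries_to_frame

logger = logging.getLogger(__name__)


@dataclass
class Comparison:
    name: str
    groups: list[str]


@dataclass
class RunConfig:
    msap_input: str | None = None
    msap_dialect: str = "long"
    comparisons: list[Comparison] = field(default_factory=list)
    qpcr_input: str | None = None
    reference_genes: list[str] = field(default_factory=list)
    qpcr_comparisons: list[tuple[str, str]] = field(default_factory=list)
    error_threshold: float = 0.05
    alpha: float = 0.05
    n_permutations: int = 10_000
    confidence: float = 0.95
    seed: int = 0
    output_dir: str = "msapkit_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        comps = [Comparison(**c) if isinstance(c, dict) else Comparison(*c)
                 for c in raw.pop("comparisons", [])]
        qcomps = [tuple(c) for c in raw.pop("qpcr_comparisons", [])]
        return cls(comparisons=comps, qpcr_comparisons=qcomps, **raw)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _derived_seed(seed: int, k: int) -> int:
    return (seed + 10_007 * (k + 1)) % (2**31)


def run_msap_analysis(config: RunConfig, dataset: MsapDataset | None = None) -> Path:
    """Run every configured MSAP comparison; returns the output directory.

    ``dataset`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.msap_input``.
    """
    if dataset is None:
        if config.msap_input is None:
            raise ConfigurationError("msap_input is required when no dataset is given")
        dataset = read_band_matrix(config.msap_input, dialect=config.msap_dialect)
    if not config.comparisons:
        raise ConfigurationError("no comparisons configured")
    available = set(dataset.group_labels)
    for comp in config.comparisons:
        if len(comp.groups) < 2:
            raise ConfigurationError(f"comparison {comp.name!r} needs >= 2 groups")
        missing = set(comp.groups) - available
        if missing:
            raise ConfigurationError(
                f"comparison {comp.name!r} references unknown group(s): "
                + ", ".join(sorted(missing))
            )
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"msapkit {__version__}",
        f"seed\t{config.seed}",
        f"error_threshold\t{config.error_threshold}",
        f"alpha\t{config.alpha}",
        f"n_permutations\t{config.n_permutations}",
    ]
    for k, comp in enumerate(config.comparisons):
        out = out_root / comp.name
        out.mkdir(parents=True, exist_ok=True)
        sub = dataset.subset_groups(comp.groups)
        types = call_methylation_types(sub)
        classification, binary = classify_loci(types, config.error_threshold)
        _write_tsv(classification.summary(), out / "locus_classification.tsv")

        ratios = global_methylation_ratio(types)
        _write_tsv(ratios.to_frame(), out / "global_methylation.tsv")
        _write_tsv(band_type_frequencies(types), out / "band_type_frequencies.tsv")

        dist = pairwise_distances(binary)
        res = amova(dist, binary.group_labels, n_permutations=config.n_permutations,
                    seed=_derived_seed(config.seed, 3 * k))
        _write_tsv(res.to_frame(), out / "amova.tsv")
        pw = pairwise_group_amova(dist, binary.group_labels,
                                  n_permutations=config.n_permutations,
                                  seed=_derived_seed(config.seed, 3 * k + 1))
        _write_tsv(pw, out / "amova_pairwise.tsv", index=False)

        ord_res = pcoa(dist)
        coords = ord_res.to_frame()
        with open(out / "pcoa.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# pct_variance\t" + "\t".join(repr(float(v)) for v in ord_res.pct_variance) + "\n")
            coords.to_csv(fh, sep="\t", lineterminator="\n")

        tests = locus_fisher_tests(binary, alpha=config.alpha,
                                   seed=_derived_seed(config.seed, 3 * k + 2))
        _write_tsv(tests.to_frame(), out / "locus_tests.tsv")

        sig = tests.significant_loci
        heat = types.restrict_loci(sig) if sig else types.restrict_loci([])
        _write_tsv(heat.to_frame().T.rename_axis("locus"), out / "heatmap_matrix.tsv")
        newick_path = out / "significant_loci_upgma.nwk"
        if len(sig) >= 2:
            tree = upgma_cluster(gower_distance(heat))
            newick = tree.to_newick()
        elif len(sig) == 1:
            newick = sig[0] + ";"
            logger.info("%s: only one significant locus; trivial tree", comp.name)
        else:
            newick = ";"
            logger.info("%s: no significant loci; empty tree", comp.name)
        newick_path.write_text(newick + "\n", encoding="utf-8")
        log_lines.append(
            f"comparison\t{comp.name}\tgroups={','.join(comp.groups)}"
            f"\tpolymorphic_msl={len(binary.locus_ids)}"
            f"\tphi_st={res.phi_st!r}\tp={res.p_perm!r}\tsignificant={len(sig)}"
        )
    (out_root / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out_root


def run_qpcr_analysis(config: RunConfig,
                      experiment: QpcrExperiment | None = None) -> Path:
    """Run the relative-expression analysis; returns the output directory."""
    if experiment is None:
        if config.qpcr_input is None:
            raise ConfigurationError("qpcr_input is required when no experiment is given")
        if len(config.reference_genes) != 2:
            raise ConfigurationError("exactly 2 reference_genes must be configured")
        experiment = QpcrExperiment.from_csv(config.qpcr_input, config.reference_genes)
    if not config.qpcr_comparisons:
        raise ConfigurationError("no qpcr_comparisons configured")
    dcq = delta_cq(experiment)
    known = set(dcq["group"])
    for t, c in config.qpcr_comparisons:
        missing = {t, c} - known
        if missing:
            raise ConfigurationError(
                "qpcr comparison references unknown group(s): " + ", ".join(sorted(missing))
            )
    summaries = expression_tests(dcq, list(config.qpcr_comparisons),
                                 confidence=config.confidence)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    _write_tsv(dcq, out_root / "dcq.tsv", index=False)
    _write_tsv(summaries_to_frame(summaries), out_root / "expression_summary.tsv",
               index=False)
    return out_root
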