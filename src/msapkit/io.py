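"""Reading and writing MSAP band-presence matrices.

An MSAP assay digests genomic DNA twice, once with HpaII + EcoRI and once
with MspI + EcoRI.  Because the two isoschizomers are blocked by different
cytosine-methylation states of the CCGG site, each anonymous locus yields a
pair of presence/absence calls per sample, one per enzyme combination.
This module holds the in-memory container for such data
(:class:`MsapDataset`), two text dialects for it, and the replicate-based
genotyping-error estimate used to pick locus-filtering thresholds.

Dialects
--------
``long``
    Comma-separated; header ``sample_id,group,enzyme,replicate_of,<locus...>``;
    exactly two rows per sample (enzyme ``HPA`` and ``MSP``); cells
    ``0``/``1``/``NA``.
``msap``
    The layout consumed by the eponymous R package: first row is the locus
    names; every following row is ``group,sample,enzyme,<0/1 cells...>``.
    Technical-replicate links are not representable in this dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

_ENZYMES = ("HPA", "MSP")


@dataclass
class MsapDataset:
    """Samples x loci presence calls for both enzyme combinations.

    Presence matrices are float DataFrames indexed by sample, with values
    ``1.0`` (band present), ``0.0`` (absent) or ``NaN`` (missing call).
    """

    sample_ids: list[str]
    group_labels: list[str]
    locus_ids: list[str]
    presence_hpa: pd.DataFrame
    presence_msp: pd.DataFrame
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    primer_combo_of_locus: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.group_labels) != len(self.sample_ids):
            raise ConfigurationError(
                "group_labels must have one label per sample "
                f"({len(self.group_labels)} labels, {len(self.sample_ids)} samples)"
            )
        for name, mat in (("presence_hpa", self.presence_hpa),
                          ("presence_msp", self.presence_msp)):
            if list(mat.index) != list(self.sample_ids):
                raise ConfigurationError(f"{name} index must equal sample_ids")
            if list(mat.columns) != list(self.locus_ids):
                raise ConfigurationError(f"{name} columns must equal locus_ids")
            vals = mat.to_numpy(dtype=float)
            ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
            if not ok.all():
                raise ConfigurationError(f"{name} cells must be 0, 1 or missing")
        known = set(self.sample_ids)
        for a, b in self.replicate_pairs:
            if a not in known or b not in known:
                raise ConfigurationError(f"replicate pair ({a}, {b}) names unknown sample")

    @property
    def groups(self) -> pd.Series:
        return pd.Series(self.group_labels, index=self.sample_ids, name="group")

    def subset_groups(self, groups: list[str]) -> "MsapDataset":
        """Restrict to samples whose group label is in ``groups`` (order kept)."""
        missing = set(groups) - set(self.group_labels)
        if missing:
            raise ConfigurationError(
                f"unknown group label(s): {', '.join(sorted(missing))}"
            )
        keep = [s for s, g in zip(self.sample_ids, self.group_labels) if g in groups]
        gmap = dict(zip(self.sample_ids, self.group_labels))
        kept = set(keep)
        pairs = [(a, b) for a, b in self.replicate_pairs if a in kept and b in kept]
        return MsapDataset(
            sample_ids=keep,
            group_labels=[gmap[s] for s in keep],
            locus_ids=list(self.locus_ids),
            presence_hpa=self.presence_hpa.loc[keep],
            presence_msp=self.presence_msp.loc[keep],
            replicate_pairs=pairs,
            primer_combo_of_locus=self.primer_combo_of_locus,
        )

    def equals(self, other: "MsapDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.group_labels == other.group_labels
            and self.locus_ids == other.locus_ids
            and sorted(map(tuple, map(sorted, self.replicate_pairs)))
            == sorted(map(tuple, map(sorted, other.replicate_pairs)))
            and np.array_equal(self.presence_hpa.to_numpy(),
                               other.presence_hpa.to_numpy(), equal_nan=True)
            and np.array_equal(self.presence_msp.to_numpy(),
                               other.presence_msp.to_numpy(), equal_nan=True)
        )


def _cell_to_float(token: str, where: str) -> float:
    token = token.strip()
    if token in ("0", "1"):
        return float(token)
    if token in ("NA", ""):
        return float("nan")
    raise FormatError(f"unknown cell value {token!r} at {where}")


def _fmt_cell(v: float) -> str:
    return "NA" if np.isnan(v) else str(int(v))


def read_band_matrix(path, dialect: str = "long") -> MsapDataset:
    """Read a band matrix file in the given dialect into an :class:`MsapDataset`.

    Every sample must carry exactly one HPA and one MSP row; violations
    raise :class:`~msapkit.errors.FormatError` naming the offending sample.
    """
    if dialect == "long":
        return _read_long(path)
    if dialect == "msap":
        return _read_msap(path)
    raise ConfigurationError(f"unknown dialect {dialect!r} (expected 'long' or 'msap')")


def write_band_matrix(dataset: MsapDataset, path, dialect: str = "long") -> None:
    """Write ``dataset`` so that :func:`read_band_matrix` reproduces it.

    The msap dialect cannot carry replicate-pair links; they are dropped
    there (the long dialect preserves them).
    """
    if dialect == "long":
        _write_long(dataset, path)
    elif dialect == "msap":
        _write_msap(dataset, path)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r} (expected 'long' or 'msap')")


def _read_long(path) -> MsapDataset:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split(",")
    if header[:4] != ["sample_id", "group", "enzyme", "replicate_of"]:
        raise FormatError(
            f"{path}: long dialect header must start with "
            "'sample_id,group,enzyme,replicate_of'"
        )
    locus_ids = header[4:]
    rows: dict[str, dict[str, np.ndarray]] = {}
    groups: dict[str, str] = {}
    rep_of: dict[str, str] = {}
    order: list[str] = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 4 + len(locus_ids):
            raise FormatError(f"{path}:{i}: expected {4 + len(locus_ids)} fields, got {len(parts)}")
        sample, group, enzyme, rep = (p.strip() for p in parts[:4])
        if enzyme not in _ENZYMES:
            raise FormatError(f"{path}:{i}: enzyme must be HPA or MSP, got {enzyme!r}")
        if sample not in rows:
            rows[sample] = {}
            order.append(sample)
            groups[sample] = group
        elif groups[sample] != group:
            raise FormatError(f"{path}: sample {sample} has conflicting group labels")
        if enzyme in rows[sample]:
            raise FormatError(f"{path}: duplicate {enzyme} row for sample {sample}")
        if rep:
            rep_of[sample] = rep
        rows[sample][enzyme] = np.array(
            [_cell_to_float(c, f"{path}:{i}") for c in parts[4:]], dtype=float
        )
    for sample in order:
        have = set(rows[sample])
        if have != set(_ENZYMES):
            missing = ", ".join(sorted(set(_ENZYMES) - have))
            raise FormatError(f"{path}: sample {sample} lacks {missing} row")
    pairs = sorted({tuple(sorted((s, r))) for s, r in rep_of.items()})
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise FormatError(f"{path}: replicate_of references unknown sample in pair ({a}, {b})")
    return MsapDataset(
        sample_ids=order,
        group_labels=[groups[s] for s in order],
        locus_ids=locus_ids,
        presence_hpa=pd.DataFrame(
            [rows[s]["HPA"] for s in order], index=order, columns=locus_ids
        ),
        presence_msp=pd.DataFrame(
            [rows[s]["MSP"] for s in order], index=order, columns=locus_ids
        ),
        replicate_pairs=[tuple(p) for p in pairs],
    )


def _write_long(ds: MsapDataset, path) -> None:
    rep_of = {}
    for a, b in ds.replicate_pairs:
        rep_of[b] = a  # second member points at the first
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["sample_id", "group", "enzyme", "replicate_of"] + list(ds.locus_ids)) + "\n")
        for s, g in zip(ds.sample_ids, ds.group_labels):
            for enzyme, mat in (("HPA", ds.presence_hpa), ("MSP", ds.presence_msp)):
                cells = [_fmt_cell(v) for v in mat.loc[s].to_numpy(dtype=float)]
                fh.write(",".join([s, g, enzyme, rep_of.get(s, "")] + cells) + "\n")


def _read_msap(path) -> MsapDataset:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    locus_ids = [t.strip() for t in lines[0].split(",") if t.strip() != ""]
    rows: dict[str, dict[str, np.ndarray]] = {}
    groups: dict[str, str] = {}
    order: list[str] = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 3 + len(locus_ids):
            raise FormatError(f"{path}:{i}: expected {3 + len(locus_ids)} fields, got {len(parts)}")
        group, sample, enzyme = (p.strip() for p in parts[:3])
        if enzyme not in _ENZYMES:
            raise FormatError(f"{path}:{i}: enzyme must be HPA or MSP, got {enzyme!r}")
        if sample not in rows:
            rows[sample] = {}
            order.append(sample)
            groups[sample] = group
        elif groups[sample] != group:
            raise FormatError(f"{path}: sample {sample} has conflicting group labels")
        if enzyme in rows[sample]:
            raise FormatError(f"{path}: duplicate {enzyme} row for sample {sample}")
        rows[sample][enzyme] = np.array(
            [_cell_to_float(c, f"{path}:{i}") for c in parts[3:]], dtype=float
        )
    for sample in order:
        have = set(rows[sample])
        if have != set(_ENZYMES):
            missing = ", ".join(sorted(set(_ENZYMES) - have))
            raise FormatError(f"{path}: sample {sample} lacks {missing} row")
    return MsapDataset(
        sample_ids=order,
        group_labels=[groups[s] for s in order],
        locus_ids=locus_ids,
        presence_hpa=pd.DataFrame(
            [rows[s]["HPA"] for s in order], index=order, columns=locus_ids
        ),
        presence_msp=pd.DataFrame(
            [rows[s]["MSP"] for s in order], index=order, columns=locus_ids
        ),
    )


def _write_msap(ds: MsapDataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(ds.locus_ids) + "\n")
        for s, g in zip(ds.sample_ids, ds.group_labels):
            for enzyme, mat in (("HPA", ds.presence_hpa), ("MSP", ds.presence_msp)):
                cells = [_fmt_cell(v) for v in mat.loc[s].to_numpy(dtype=float)]
                fh.write(",".join([g, s, enzyme] + cells) + "\n")


def estimate_genotyping_error(dataset: MsapDataset) -> pd.Series:
    """Replicate-concordance genotyping error per primer combination.

    For every technical-replicate pair, band-presence calls from both
    enzyme combinations are compared locus by locus; calls where either
    member is missing are excluded pairwise.  The error rate is
    discordant calls / compared calls, the standard dominant-marker
    (AFLP/MSAP) error-rate definition.  Returned as a Series indexed by
    primer-combination label ("all" when loci carry no combo annotation).
    """
    if not dataset.replicate_pairs:
        raise ConfigurationError("estimate_genotyping_error requires replicate_pairs")
    combos = dataset.primer_combo_of_locus or {}
    combo_of = np.array([combos.get(l, "all") for l in dataset.locus_ids])
    labels = sorted(set(combo_of))
    mism = {c: 0 for c in labels}
    comp = {c: 0 for c in labels}
    for a, b in dataset.replicate_pairs:
        for mat in (dataset.presence_hpa, dataset.presence_msp):
            va = mat.loc[a].to_numpy(dtype=float)
            vb = mat.loc[b].to_numpy(dtype=float)
            ok = ~np.isnan(va) & ~np.isnan(vb)
            for c in labels:
                sel = ok & (combo_of == c)
                comp[c] += int(sel.sum())
                mism[c] += int((va[sel] != vb[sel]).sum())
    rates = {}
    for c in labels:
        rates[c] = mism[c] / comp[c] if comp[c] else float("nan")
    return pd.Series(rates, name="genotyping_error").sort_index()
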