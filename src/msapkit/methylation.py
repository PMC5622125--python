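"""Methylation typing of two-enzyme band patterns and locus classification.

HpaII and MspI both recognise CCGG but are blocked by different cytosine
methylation states, so the pair of presence calls at a locus encodes one
of four states:

===========  ===========  ========  ==========================================
HpaII band   MspI band    Type      interpretation
===========  ===========  ========  ==========================================
present      present      I         unmethylated
absent       present      II        internal cytosine methylation
present      absent       III       hemi-methylated outer cytosine
absent       absent       IV        hypermethylated (or target absent)
===========  ===========  ========  ==========================================

Loci whose methylated proportion exceeds an error threshold are deemed
methylation-susceptible (MSL); the polymorphic subset is recoded to a
binary methylated/unmethylated matrix, the input of the differentiation
analyses.  Type IV is counted as methylated in the binary matrix even
though an (absent, absent) pattern can also reflect sequence absence; this
follows the field's "full methylation" scoring convention and is a
documented caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedValueError
from .io import MsapDataset

logger = logging.getLogger(__name__)

#: numeric codes used in the type matrix
TYPE_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV"}

#: methylation type -> (HpaII presence, MspI presence)
TYPE_TO_PRESENCE = {1: (1, 1), 2: (0, 1), 3: (1, 0), 4: (0, 0)}


@dataclass
class MethylationTypeMatrix:
    """Samples x loci methylation types, coded 1-4 with NaN for missing."""

    sample_ids: list[str]
    group_labels: list[str]
    locus_ids: list[str]
    types: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        return pd.Series(self.group_labels, index=self.sample_ids, name="group")

    def restrict_loci(self, loci: list[str]) -> "MethylationTypeMatrix":
        return MethylationTypeMatrix(
            sample_ids=list(self.sample_ids),
            group_labels=list(self.group_labels),
            locus_ids=list(loci),
            types=self.types[list(loci)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Roman-numeral coded export (NA for missing)."""
        return self.types.map(lambda v: "NA" if np.isnan(v) else TYPE_LABELS[int(v)])


@dataclass
class LocusClassification:
    locus_ids: list[str]
    is_msl: pd.Series          # bool per locus
    is_polymorphic: pd.Series  # bool per locus; implies is_msl
    error_threshold: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"is_msl": self.is_msl, "is_polymorphic": self.is_polymorphic}
        ).rename_axis("locus")


@dataclass
class MslBinaryMatrix:
    """Polymorphic MSL recoded 1 = methylated (types II-IV), 0 = unmethylated."""

    sample_ids: list[str]
    group_labels: list[str]
    locus_ids: list[str]
    states: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        return pd.Series(self.group_labels, index=self.sample_ids, name="group")


def call_methylation_types(dataset: MsapDataset) -> MethylationTypeMatrix:
    """Map each (HpaII, MspI) presence pair to a methylation type.

    A cell is missing iff either enzyme call is missing.
    """
    h = dataset.presence_hpa.to_numpy(dtype=float)
    m = dataset.presence_msp.to_numpy(dtype=float)
    types = np.full(h.shape, np.nan)
    complete = ~np.isnan(h) & ~np.isnan(m)
    # type code = 1 + (1-h) + 2*(1-m) reproduces the pattern table above
    code = 1 + (1 - h) + 2 * (1 - m)
    types[complete] = code[complete]
    return MethylationTypeMatrix(
        sample_ids=list(dataset.sample_ids),
        group_labels=list(dataset.group_labels),
        locus_ids=list(dataset.locus_ids),
        types=pd.DataFrame(types, index=dataset.sample_ids, columns=dataset.locus_ids),
    )


def classify_loci(
    types: MethylationTypeMatrix, error_threshold: float = 0.05
) -> tuple[LocusClassification, MslBinaryMatrix]:
    """Split loci into MSL/NML and build the polymorphic-MSL binary matrix.

    A locus is MSL iff the proportion of non-missing samples with type in
    {II, III, IV} strictly exceeds ``error_threshold``; an MSL is retained
    as polymorphic iff both binary states each occur in strictly more than
    ``error_threshold`` of its non-missing samples.  The threshold-on-both-
    states rule (rather than ">=1 discordant sample") keeps loci whose
    apparent polymorphism could be pure scoring error out of the analysis.
    Loci with all cells missing are excluded and logged.
    """
    if not 0 <= error_threshold < 1:
        raise ConfigurationError(f"error_threshold must be in [0, 1), got {error_threshold}")
    t = types.types.to_numpy(dtype=float)
    nonmiss = ~np.isnan(t)
    n_obs = nonmiss.sum(axis=0)
    all_missing = n_obs == 0
    if all_missing.any():
        bad = [l for l, a in zip(types.locus_ids, all_missing) if a]
        logger.warning("excluding %d locus/loci with all cells missing: %s",
                       len(bad), ", ".join(bad))
    meth = nonmiss & (t >= 2)          # types II, III, IV
    unmeth = nonmiss & (t == 1)        # type I
    with np.errstate(invalid="ignore", divide="ignore"):
        p_meth = np.where(n_obs > 0, meth.sum(axis=0) / np.maximum(n_obs, 1), np.nan)
        p_unmeth = np.where(n_obs > 0, unmeth.sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    is_msl = (~all_missing) & (p_meth > error_threshold)
    is_poly = is_msl & (p_unmeth > error_threshold) & (p_meth > error_threshold)
    classification = LocusClassification(
        locus_ids=list(types.locus_ids),
        is_msl=pd.Series(is_msl, index=types.locus_ids, name="is_msl"),
        is_polymorphic=pd.Series(is_poly, index=types.locus_ids, name="is_polymorphic"),
        error_threshold=error_threshold,
    )
    keep = [l for l, p in zip(types.locus_ids, is_poly) if p]
    states = np.where(np.isnan(t), np.nan, (t >= 2).astype(float))
    binary = MslBinaryMatrix(
        sample_ids=list(types.sample_ids),
        group_labels=list(types.group_labels),
        locus_ids=keep,
        states=pd.DataFrame(states, index=types.sample_ids,
                            columns=types.locus_ids)[keep],
    )
    return classification, binary


def global_methylation_ratio(types: MethylationTypeMatrix) -> pd.Series:
    """Per-sample global methylation: (II + III) / (I + II + III).

    Type IV cells are excluded from numerator and denominator because an
    (absent, absent) pattern is uninformative about the ratio's scale
    (hypermethylation vs. sequence absence).  A sample with no scorable
    informative loci (denominator 0) raises
    :class:`~msapkit.errors.UndefinedValueError`.
    """
    t = types.types.to_numpy(dtype=float)
    n1 = (t == 1).sum(axis=1)
    n2 = (t == 2).sum(axis=1)
    n3 = (t == 3).sum(axis=1)
    denom = n1 + n2 + n3
    bad = denom == 0
    if bad.any():
        names = [s for s, b in zip(types.sample_ids, bad) if b]
        raise UndefinedValueError(
            "global methylation ratio undefined (no Type I-III loci) for "
            "sample(s): " + ", ".join(names)
        )
    return pd.Series((n2 + n3) / denom, index=types.sample_ids,
                     name="global_methylation_ratio")


def band_type_frequencies(types: MethylationTypeMatrix) -> pd.DataFrame:
    """Counts of Types I-IV per group over non-missing cells.

    Rows are groups, columns the four types; each row sums to the group's
    non-missing cell count.
    """
    t = types.types.to_numpy(dtype=float)
    groups = np.array(types.group_labels)
    out = {}
    for g in pd.unique(groups):
        sel = t[groups == g]
        out[g] = [int((sel == k).sum()) for k in (1, 2, 3, 4)]
    return pd.DataFrame.from_dict(
        out, orient="index", columns=[TYPE_LABELS[k] for k in (1, 2, 3, 4)]
    ).rename_axis("group")
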