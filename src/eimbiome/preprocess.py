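"""ASV filtering and negative-control decontamination.

Three rules are applied downstream of denoising, in this order:

1. drop globally rare ASVs whose pooled relative abundance is below
   0.001% of all reads (:func:`filter_low_frequency`);
2. remove reagent background using negative controls: ASVs present in
   >15% of controls but <15% of biological samples are dropped
   outright, and the mean control count of every surviving ASV is
   subtracted from the biological counts
   (:func:`remove_control_artifacts`);
3. for differential abundance and network inference only, drop ASVs
   present in <10% of samples (:func:`prevalence_filter`).

"Present" means count > 0 throughout, and all prevalence comparisons
are strict, matching the wording of the source protocol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountTable, validate_metadata

__all__ = [
    "filter_low_frequency",
    "remove_control_artifacts",
    "prevalence_filter",
    "relative_abundance",
]


def filter_low_frequency(counts: CountTable, threshold: float = 1e-5) -> CountTable:
    """Drop ASVs whose pooled relative abundance is strictly below ``threshold``.

    The pooled abundance of an ASV is its total count over all samples
    divided by the grand total.  The default 1e-5 is the 0.001% cutoff.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    if counts.n_asvs == 0 or counts.n_samples == 0:
        raise ValueError("empty count table")
    totals = counts.data.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("count table contains no reads")
    keep = totals / grand >= threshold
    return CountTable(counts.data.loc[:, keep])


def remove_control_artifacts(
    counts: CountTable,
    meta: pd.DataFrame,
    control_prevalence: float = 0.15,
    sample_prevalence: float = 0.15,
) -> CountTable:
    """Decontaminate using negative controls.

    An ASV present (count > 0) in strictly more than
    ``control_prevalence`` of negative controls AND strictly fewer than
    ``sample_prevalence`` of biological samples is removed outright.
    For every remaining ASV, its mean count across controls is
    subtracted from each biological sample's count, clamped at zero and
    rounded half away from zero so the table stays integer.  Control
    samples are dropped from the output.
    """
    meta = validate_metadata(meta, counts)
    flags = meta.loc[counts.sample_ids, "is_negative_control"].to_numpy(bool)
    bio_ids = [s for s, f in zip(counts.sample_ids, flags) if not f]
    ctrl_ids = [s for s, f in zip(counts.sample_ids, flags) if f]
    if not bio_ids:
        raise ValueError("count table contains no biological samples")
    bio = counts.data.loc[bio_ids]
    if not ctrl_ids:
        return CountTable(bio)
    ctrl = counts.data.loc[ctrl_ids]

    prev_ctrl = (ctrl > 0).mean(axis=0)
    prev_bio = (bio > 0).mean(axis=0)
    drop = (prev_ctrl > control_prevalence) & (prev_bio < sample_prevalence)
    keep = bio.columns[~drop]

    corrected = bio[keep].to_numpy(float) - ctrl[keep].mean(axis=0).to_numpy()
    corrected = np.floor(np.clip(corrected, 0.0, None) + 0.5)  # half away from zero
    return CountTable(pd.DataFrame(corrected, index=bio.index, columns=keep, dtype=np.int64))


def prevalence_filter(counts: CountTable, min_prevalence: float = 0.10) -> CountTable:
    """Drop ASVs present in strictly fewer than ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    if counts.n_asvs == 0 or counts.n_samples == 0:
        raise ValueError("empty count table")
    prevalence = (counts.data > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    return CountTable(counts.data.loc[:, keep])


def relative_abundance(counts: CountTable) -> pd.DataFrame:
    """Per-sample fractions; each row sums to one."""
    return counts.relative_abundance()
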