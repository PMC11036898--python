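"""Synthetic fecal-community generator with planted, recoverable structure.

Real 16S data for the IBD cohort this package targets is not publicly
deposited, so every statistical property the pipeline relies on is
planted explicitly here and recorded in a :class:`SyntheticTruth`:

* a multivariate log-normal "basis" community whose log-scale
  correlation matrix contains block-diagonal modules (the structure
  SparCC estimates),
* group log2-fold effects on chosen ASVs, optionally with
  group-specific structural zeros (the regime that separates the
  zero-inflated negative binomial from the plain one),
* contaminant ASVs concentrated in negative controls with occasional
  carryover into biological samples (the regime the decontamination
  rules remove),
* an enrollment fixture reproducing the cohort bookkeeping of the
  study population (156 enrolled, 25 excluded as unconfirmed,
  86 EIM vs 45 control).

Counts are multinomial draws from the per-sample basis fractions at a
negative-binomially distributed sequencing depth, so row sums equal
library sizes exactly and sampling zeros arise naturally on top of any
structural ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import GROUP_CASE, GROUP_CONTROL, CountTable

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "CohortRecord",
    "generate_community",
    "generate_negative_controls",
    "apply_contaminant_carryover",
    "generate_random_tree",
    "make_cohort_fixture",
]

# log-scale spread of baseline ASV abundances; ~3 orders of magnitude
# between common and rare taxa, typical of stool 16S profiles
_BASELINE_LOG_SD = 1.5
# within-sample log-normal sd of each basis abundance
_BASIS_LOG_SD = 1.0
_DEPTH_FLOOR = 1000


@dataclass
class SimulationParams:
    """Knobs of the community generator.

    ``module_spec`` entries are ``(size, rho)``: a block of `size` ASVs
    with pairwise log-basis correlation `rho` in (0, 1).  Blocks occupy
    consecutive ASV indices starting at 0, in order.

    ``effect_spec`` entries are ``(asv_index, log2_effect, zero_prob)``
    where ``zero_prob`` is either one probability (both groups) or a
    ``(case, control)`` pair of structural-zero probabilities.

    ``contaminant_spec`` entries are ``(asv_index, control_mean,
    carryover_prob)``: expected reads in a negative control and the
    per-biological-sample probability of reagent carryover.
    """

    n_samples_per_group: int | tuple[int, int] = (86, 45)
    n_asvs: int = 300
    n_controls: int = 8
    depth_mean: float = 30_000.0
    depth_dispersion: float = 5.0
    module_spec: Sequence[tuple[int, float]] = field(default_factory=tuple)
    effect_spec: Sequence[tuple] = field(default_factory=tuple)
    contaminant_spec: Sequence[tuple[int, float, float]] = field(default_factory=tuple)
    seed: int = 0

    def group_sizes(self) -> tuple[int, int]:
        n = self.n_samples_per_group
        return (n, n) if isinstance(n, int) else (int(n[0]), int(n[1]))

    def module_index_blocks(self) -> list[np.ndarray]:
        blocks, start = [], 0
        for size, _ in self.module_spec:
            blocks.append(np.arange(start, start + size))
            start += size
        return blocks

    def validate(self) -> None:
        n_case, n_ctrl = self.group_sizes()
        if min(n_case, n_ctrl) < 1 or self.n_asvs < 1:
            raise ValueError("sample and ASV counts must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be non-negative")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        total_module = 0
        for size, rho in self.module_spec:
            if size < 2:
                raise ValueError("module size must be >= 2")
            if not 0.0 < rho < 1.0:
                raise ValueError(f"module correlation {rho} outside (0, 1)")
            total_module += size
        if total_module > self.n_asvs:
            raise ValueError("module sizes exceed n_asvs")
        module_idx = set(range(total_module))
        for entry in self.effect_spec:
            idx, _, zp = _unpack_effect(entry)
            if not 0 <= idx < self.n_asvs:
                raise ValueError(f"effect index {idx} out of range")
            if idx in module_idx:
                raise ValueError(
                    f"effect on ASV index {idx} overlaps a planted module; "
                    "this would confound module-recovery tests"
                )
            for p in zp:
                if not 0.0 <= p <= 1.0:
                    raise ValueError("structural-zero probability outside [0, 1]")
        for idx, mean, prob in self.contaminant_spec:
            if not 0 <= idx < self.n_asvs:
                raise ValueError(f"contaminant index {idx} out of range")
            if mean < 0 or not 0.0 <= prob <= 1.0:
                raise ValueError("invalid contaminant spec entry")


def _unpack_effect(entry) -> tuple[int, float, tuple[float, float]]:
    idx, lfc, zp = entry
    if np.isscalar(zp):
        zp = (float(zp), float(zp))
    return int(idx), float(lfc), (float(zp[0]), float(zp[1]))


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`generate_community`."""

    basis_correlation: pd.DataFrame
    planted_effects: dict[str, float]
    module_membership: dict[str, int]
    #: log-scale basis draws (before structural zeros), kept only when
    #: generate_community(record_basis=True); used by recovery tests
    log_basis: pd.DataFrame | None = None

    def module_members(self, module_id: int) -> list[str]:
        return [a for a, m in self.module_membership.items() if m == module_id]


def _asv_ids(n: int) -> list[str]:
    return [f"ASV_{i + 1:04d}" for i in range(n)]


def _target_correlation(params: SimulationParams) -> np.ndarray:
    corr = np.eye(params.n_asvs)
    for block, (size, rho) in zip(params.module_index_blocks(), params.module_spec):
        corr[np.ix_(block, block)] = rho
        corr[block, block] = 1.0
    return corr


def generate_community(
    params: SimulationParams, record_basis: bool = False
) -> tuple[CountTable, pd.DataFrame, SyntheticTruth]:
    """Draw a sample x ASV count table with planted structure.

    Returns the counts, a metadata frame (group, subtype, surgery,
    negative-control flag) and the :class:`SyntheticTruth`.  Identical
    parameters (including ``seed``) give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_case, n_ctrl = params.group_sizes()
    n = n_case + n_ctrl
    d = params.n_asvs
    asvs = _asv_ids(d)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_case] = True

    corr = _target_correlation(params)
    chol = np.linalg.cholesky(corr)
    baseline = rng.normal(0.0, _BASELINE_LOG_SD, size=d)

    log_basis = baseline + _BASIS_LOG_SD * (rng.standard_normal((n, d)) @ chol.T)
    for entry in params.effect_spec:
        idx, lfc, _ = _unpack_effect(entry)
        log_basis[is_case, idx] += lfc * np.log(2.0)
    basis = np.exp(log_basis)

    for entry in params.effect_spec:
        idx, _, (p_case, p_ctrl) = _unpack_effect(entry)
        zero_prob = np.where(is_case, p_case, p_ctrl)
        basis[rng.random(n) < zero_prob, idx] = 0.0

    # contaminant ASVs are reagent signal, not community members: they
    # enter biological samples only through carryover
    for idx, _, _ in params.contaminant_spec:
        basis[:, idx] = 0.0

    depths = _draw_depths(rng, n, params.depth_mean, params.depth_dispersion)
    counts = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        total = basis[i].sum()
        frac = basis[i] / total if total > 0 else np.full(d, 1.0 / d)
        counts[i] = rng.multinomial(depths[i], frac)

    table = CountTable(pd.DataFrame(counts, index=samples, columns=asvs))
    meta = pd.DataFrame(
        {
            "group": np.where(is_case, GROUP_CASE, GROUP_CONTROL),
            "subtype": rng.choice(["CD", "UC"], size=n, p=[0.62, 0.38]),
            "surgery": rng.random(n) < 0.34,
            "is_negative_control": False,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = SyntheticTruth(
        basis_correlation=pd.DataFrame(corr, index=asvs, columns=asvs),
        planted_effects={
            asvs[_unpack_effect(e)[0]]: _unpack_effect(e)[1] for e in params.effect_spec
        },
        module_membership={
            asvs[i]: m
            for m, block in enumerate(params.module_index_blocks())
            for i in block
        },
        log_basis=(
            pd.DataFrame(log_basis, index=samples, columns=asvs)
            if record_basis
            else None
        ),
    )
    return table, meta, truth


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    depths = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(depths, _DEPTH_FLOOR)


def generate_negative_controls(truth: SyntheticTruth, params: SimulationParams) -> CountTable:
    """Negative-control samples: blank except contaminant ASVs.

    Contaminant counts are Poisson at the stated per-control mean.  The
    stream is derived from ``params.seed`` but distinct from the one
    used by :func:`generate_community`.
    """
    rng = np.random.default_rng([params.seed, 1])
    asvs = list(truth.basis_correlation.index)
    ids = [f"NC{i + 1:03d}" for i in range(params.n_controls)]
    counts = np.zeros((params.n_controls, len(asvs)), dtype=np.int64)
    if params.n_controls:
        for idx, mean, _ in params.contaminant_spec:
            counts[:, idx] = rng.poisson(mean, size=params.n_controls)
    return CountTable(pd.DataFrame(counts, index=ids, columns=asvs))


def apply_contaminant_carryover(
    counts: CountTable, params: SimulationParams
) -> CountTable:
    """Add reagent carryover of contaminant ASVs into biological samples.

    Each sample independently receives a Poisson draw at the contaminant's
    control mean with the stated carryover probability.
    """
    rng = np.random.default_rng([params.seed, 2])
    data = counts.data.copy()
    n = counts.n_samples
    for idx, mean, prob in params.contaminant_spec:
        hit = rng.random(n) < prob
        data.iloc[:, idx] += np.where(hit, rng.poisson(mean, size=n), 0)
    return CountTable(data)


def generate_random_tree(asv_ids: Sequence[str], seed: int) -> TreeNode:
    """Random rooted binary tree over ``asv_ids`` with positive lengths.

    Built by repeated random joins (a Yule-like topology); branch
    lengths are exponential with a small floor so none is zero.
    """
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 leaf identifiers")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate leaf identifiers")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=i, length=round(rng.exponential(0.1) + 0.01, 6)) for i in ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=round(rng.exponential(0.1) + 0.01, 6))
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


@dataclass
class CohortRecord:
    """One enrolled participant of the cohort fixture."""

    participant_id: str
    subtype: str  # CD | UC
    eim_status: str  # confirmed | unconfirmed | none
    n_eims: int
    sex: str  # F | M
    surgery: bool
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.eim_status == "none" and self.n_eims != 0:
            raise ValueError("eim_status none requires n_eims == 0")
        if self.eim_status == "unconfirmed" and not self.excluded_reason:
            raise ValueError("unconfirmed records must carry excluded_reason")


# Enrollment marginals of the study population: 156 enrolled, 25 excluded
# pending specialist confirmation; of the 131 analysed, 86 with confirmed
# EIMs (60 CD / 26 UC, 52 female) and 45 without (21 CD / 24 UC, 18 female).
_COHORT_PLAN = [
    # (eim_status, subtype, n_total, n_female, n_surgery)
    ("confirmed", "CD", 60, 36, 29),
    ("confirmed", "UC", 26, 16, 3),
    ("none", "CD", 21, 9, 12),
    ("none", "UC", 24, 9, 0),
]
_N_UNCONFIRMED = 25


def make_cohort_fixture(seed: int) -> list[CohortRecord]:
    """156 enrollment records matching the study's group marginals."""
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for status, subtype, n_total, n_female, n_surgery in _COHORT_PLAN:
        sexes = ["F"] * n_female + ["M"] * (n_total - n_female)
        surgeries = [True] * n_surgery + [False] * (n_total - n_surgery)
        rng.shuffle(surgeries)
        for sex, surg in zip(sexes, surgeries):
            n_eims = 0
            if status == "confirmed":
                n_eims = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
            records.append(
                CohortRecord("", subtype, status, n_eims, sex, bool(surg))
            )
    for _ in range(_N_UNCONFIRMED):
        records.append(
            CohortRecord(
                "",
                str(rng.choice(["CD", "UC"], p=[0.62, 0.38])),
                "unconfirmed",
                int(rng.choice([1, 2], p=[0.8, 0.2])),
                str(rng.choice(["F", "M"])),
                bool(rng.random() < 0.3),
                excluded_reason="EIM diagnosis pending specialist confirmation",
            )
        )
    rng.shuffle(records)
    for i, rec in enumerate(records):
        rec.participant_id = f"P{i + 1:03d}"
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Tabular view of cohort records (one row per participant)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "subtype": r.subtype,
                "eim_status": r.eim_status,
                "n_eims": r.n_eims,
                "sex": r.sex,
                "surgery": r.surgery,
                "excluded_reason": r.excluded_reason or "",
            }
            for r in records
        ]
    ).set_index("participant_id")
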