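"""qPCR / RNA-seq fold-change concordance with a bootstrap comparison.

Quantitative PCR cycle thresholds (Ct) are converted to abundance fold
changes with the delta-Ct model FC = 2^(Ct_control - Ct_target),
amplification efficiency fixed at 2.  RPKM fold changes are simple
ratios.  A bootstrap over target genes then asks which sequencing
protocol's RPKM fold changes agree better with the qPCR fold changes:
each replicate resamples the target genes with replacement, expands them
over (internal control, qPCR replicate), and computes the Pearson
correlation of log2 fold changes against the strand-specific and the
non-strand-specific RPKM fold changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrTable:
    """Replicate Ct values per gene, with target / internal-control roles."""

    ct: pd.DataFrame  # index: gene; columns: Ct1..CtK
    roles: dict[str, str]  # gene -> {"target", "internal_control"}

    def __post_init__(self) -> None:
        if (self.ct <= 0).any().any():
            raise ValueError("all Ct values must be positive")
        if "target" not in self.roles.values() or "internal_control" not in self.roles.values():
            raise ValueError("need at least one target and one internal control")

    @property
    def targets(self) -> list[str]:
        return [g for g in self.ct.index if self.roles[g] == "target"]

    @property
    def controls(self) -> list[str]:
        return [g for g in self.ct.index if self.roles[g] == "internal_control"]

    @property
    def n_replicates(self) -> int:
        return self.ct.shape[1]


@dataclass
class FoldChange:
    target: str
    control: str
    replicate: int | None  # None for RPKM-derived fold changes
    fc: float


@dataclass
class FoldChangeSet:
    source: str  # {"ct", "rpkm_ss", "rpkm_nss"}
    values: list[FoldChange] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    def as_lookup(self) -> dict[tuple[str, str, int | None], float]:
        return {(v.target, v.control, v.replicate): v.fc for v in self.values}


def load_qpcr_table(path) -> QpcrTable:
    """Load a qPCR TSV with columns gene, role, Ct1..CtK."""
    df = pd.read_csv(path, sep="\t")
    ct_cols = [c for c in df.columns if c.lower().startswith("ct")]
    if not ct_cols:
        raise ValueError("no Ct columns found")
    if df[ct_cols].isna().any().any():
        bad = df.loc[df[ct_cols].isna().any(axis=1), "gene"].tolist()
        raise ValueError(f"missing Ct value(s) for gene(s): {bad}")
    ct = df.set_index("gene")[ct_cols]
    roles = dict(zip(df["gene"], df["role"]))
    return QpcrTable(ct=ct, roles=roles)


def load_packaged_qpcr_table() -> tuple[QpcrTable, pd.DataFrame]:
    """Load the packaged 12-gene qPCR fixture (9 antisense-overlapped
    targets, 3 nonoverlapped internal controls, 3 qPCR replicates each,
    plus SS and NSS RPKM per gene).

    Returns the QpcrTable and the full DataFrame (with rpkm_ss/rpkm_nss).
    """
    ref = importlib.resources.files("strandcheck.data") / "qpcr_fixture.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
        table = load_qpcr_table(path)
    return table, df


def ct_fold_changes(table: QpcrTable) -> FoldChangeSet:
    """Delta-Ct abundance fold changes: FC = 2^(Ct_control - Ct_target).

    One value per (target, control, replicate): with 9 targets, 3
    controls and 3 replicates this yields 81 fold changes.  Missing Ct
    values raise an error naming the gene and replicate.
    """
    out = FoldChangeSet(source="ct")
    for target in table.targets:
        for control in table.controls:
            for rep_idx, col in enumerate(table.ct.columns, start=1):
                ct_t = table.ct.loc[target, col]
                ct_c = table.ct.loc[control, col]
                if pd.isna(ct_t):
                    raise ValueError(f"missing Ct for {target} replicate {rep_idx}")
                if pd.isna(ct_c):
                    raise ValueError(f"missing Ct for {control} replicate {rep_idx}")
                out.values.append(
                    FoldChange(target, control, rep_idx, 2.0 ** (ct_c - ct_t))
                )
    return out


def rpkm_fold_changes(
    rpkm: Mapping[str, float],
    targets: Sequence[str],
    controls: Sequence[str],
    source: str = "rpkm",
) -> FoldChangeSet:
    """RPKM fold changes FC = rpkm_target / rpkm_control per (target, control)."""
    out = FoldChangeSet(source=source)
    for target in targets:
        for control in controls:
            denom = rpkm[control]
            if denom == 0:
                raise ValueError(f"control {control} has zero RPKM")
            out.values.append(FoldChange(target, control, None, rpkm[target] / denom))
    return out


@dataclass
class BootstrapResult:
    r_ss: np.ndarray  # per-replicate correlation, Ct vs SS RPKM fold changes
    r_nss: np.ndarray
    p_value: float  # paired two-sided t-test across bootstrap replicates
    fraction_ss_higher: float

    @property
    def mean_r_ss(self) -> float:
        return float(np.mean(self.r_ss))

    @property
    def mean_r_nss(self) -> float:
        return float(np.mean(self.r_nss))


def bootstrap_compare(
    ct_fc: FoldChangeSet,
    ss_fc: FoldChangeSet,
    nss_fc: FoldChangeSet,
    reps: int = 100,
    seed: int | None = None,
    max_redraws: int = 1000,
    unit: str = "gene",
) -> BootstrapResult:
    """Bootstrap the Ct-vs-RPKM fold-change correlations over target genes.

    Each replicate resamples the target genes with replacement and, over
    the resampled genes' (control, qPCR replicate) expansions, computes
    the Pearson correlation of log2 Ct fold change against log2 SS and
    log2 NSS RPKM fold change.  With ``unit="fold_change"`` the
    resampling unit is the individual (target, control) fold-change pair
    instead of the gene; this trades some statistical honesty (the 27
    pairs are not independent) for lower replicate-to-replicate variance.
    Replicates with fewer than 3 distinct units are redrawn (up to
    ``max_redraws`` attempts in total).  Returns the per-replicate
    correlation pairs, a paired two-sided t-test p-value across
    replicates, and the fraction of replicates where the SS correlation
    exceeds the NSS one.
    """
    if unit not in ("gene", "fold_change"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    rng = np.random.default_rng(seed)
    ct_lookup = ct_fc.as_lookup()
    ss_lookup = {(v.target, v.control): v.fc for v in ss_fc.values}
    nss_lookup = {(v.target, v.control): v.fc for v in nss_fc.values}

    targets = sorted({v.target for v in ct_fc.values})
    controls = sorted({v.control for v in ct_fc.values})
    replicates = sorted({v.replicate for v in ct_fc.values})
    if unit == "gene":
        expansions = {g: [(g, c) for c in controls] for g in targets}
        units: list = targets
    else:
        units = sorted(ss_lookup)
        expansions = {u: [u] for u in units}

    r_ss = np.empty(reps)
    r_nss = np.empty(reps)
    redraws = 0
    i = 0
    while i < reps:
        sample = [units[j] for j in rng.integers(0, len(units), size=len(units))]
        if len(set(sample)) < 3:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap draws")
            continue
        x, ys, yn = [], [], []
        for u in sample:
            for gene, control in expansions[u]:
                for rep_idx in replicates:
                    x.append(np.log2(ct_lookup[(gene, control, rep_idx)]))
                    ys.append(np.log2(ss_lookup[(gene, control)]))
                    yn.append(np.log2(nss_lookup[(gene, control)]))
        r_ss[i] = stats.pearsonr(x, ys).statistic
        r_nss[i] = stats.pearsonr(x, yn).statistic
        i += 1

    if reps < 2:
        p = float("nan")
    elif np.allclose(r_ss, r_nss):
        p = 1.0
    else:
        p = float(stats.ttest_rel(r_ss, r_nss).pvalue)
    return BootstrapResult(
        r_ss=r_ss,
        r_nss=r_nss,
        p_value=p,
        fraction_ss_higher=float(np.mean(r_ss > r_nss)),
    )
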