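"""qPCR fold-induction by the comparative-Ct (delta-delta-Ct) method.

Target-gene expression is normalized against a reference gene (classically
recA) within each condition, and fold induction compares treatment with
control:

    ddCt_r = (Ct_target,trt - Ct_ref,trt)_r - (Ct_target,ctl - Ct_ref,ctl)_r
    fold_r = E ** (-ddCt_r)

per replicate ``r``, with amplification efficiency ``E`` (2.0 = perfect
doubling each cycle).  The reported value is the mean +- sample SD of the
per-replicate folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class QpcrSample:
    """Replicate Ct values for one gene under one condition at one timepoint."""

    gene: str
    condition: str      # "treatment" or "control"
    timepoint: float    # hours
    ct: tuple[float, ...]

    def __post_init__(self):
        if not self.ct:
            raise ValueError("at least one Ct replicate required")
        if any(c <= 0 for c in self.ct):
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class FoldInduction:
    gene: str
    timepoint: float
    fold: float
    sd: float
    n: int


def _check_match(a: QpcrSample, b: QpcrSample):
    if a.timepoint != b.timepoint:
        raise ValueError(f"timepoint mismatch: {a.timepoint} vs {b.timepoint}")


def fold_induction(
    target_trt: QpcrSample,
    target_ctl: QpcrSample,
    ref_trt: QpcrSample,
    ref_ctl: QpcrSample,
    efficiency: float = 2.0,
) -> FoldInduction:
    """Fold induction of a target gene, normalized to the reference gene.

    Replicates are paired by index; all four samples must therefore carry the
    same number of replicates.
    """
    _check_match(target_trt, target_ctl)
    _check_match(target_trt, ref_trt)
    _check_match(target_trt, ref_ctl)
    ns = {len(s.ct) for s in (target_trt, target_ctl, ref_trt, ref_ctl)}
    if len(ns) != 1:
        raise ValueError(f"replicate counts differ across samples: {sorted(ns)}")
    n = ns.pop()
    folds = []
    for r in range(n):
        ddct = (target_trt.ct[r] - ref_trt.ct[r]) - (target_ctl.ct[r] - ref_ctl.ct[r])
        folds.append(efficiency ** (-ddct))
    mean = sum(folds) / n
    sd = math.sqrt(sum((f - mean) ** 2 for f in folds) / (n - 1)) if n > 1 else 0.0
    return FoldInduction(
        gene=target_trt.gene, timepoint=target_trt.timepoint,
        fold=mean, sd=sd, n=n,
    )


def read_ct_table(path) -> list[QpcrSample]:
    """Read a CSV with columns gene, condition, timepoint_h, replicate, ct."""
    df = pd.read_csv(path)
    required = {"gene", "condition", "timepoint_h", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    samples = []
    for (gene, cond, tp), grp in df.groupby(["gene", "condition", "timepoint_h"]):
        grp = grp.sort_values("replicate")
        samples.append(
            QpcrSample(
                gene=str(gene), condition=str(cond), timepoint=float(tp),
                ct=tuple(float(c) for c in grp["ct"]),
            )
        )
    return samples


def fold_table(
    samples: list[QpcrSample],
    reference_gene: str = "recA",
    efficiency: float = 2.0,
) -> list[FoldInduction]:
    """Compute fold inductions for every gene x timepoint in a sample set."""
    index = {(s.gene, s.condition, s.timepoint): s for s in samples}
    genes = sorted({s.gene for s in samples})
    tps = sorted({s.timepoint for s in samples})
    folds = []
    for gene in genes:
        for tp in tps:
            try:
                folds.append(
                    fold_induction(
                        index[(gene, "treatment", tp)],
                        index[(gene, "control", tp)],
                        index[(reference_gene, "treatment", tp)],
                        index[(reference_gene, "control", tp)],
                        efficiency=efficiency,
                    )
                )
            except KeyError:
                continue
    return folds


def format_induction_table(
    folds: list[FoldInduction], reference_gene: str = "recA"
) -> pd.DataFrame:
    """Genes x timepoints grid of "mean (+/-SD)" cells, one decimal.

    The reference gene (fold identically 1 by construction) is pinned as the
    last row and printed integer-style.
    """
    tps = sorted({f.timepoint for f in folds})
    genes = sorted({f.gene for f in folds if f.gene != reference_gene})
    if any(f.gene == reference_gene for f in folds):
        genes.append(reference_gene)
    cells = {(f.gene, f.timepoint): f for f in folds}

    def fmt(f: FoldInduction) -> str:
        if f.gene == reference_gene:
            return f"{f.fold:.0f} (+/-{f.sd:.2f})"
        return f"{f.fold:.1f} (+/-{f.sd:.1f})"

    rows = []
    for gene in genes:
        row = {"gene": gene}
        for tp in tps:
            f = cells.get((gene, tp))
            row[f"{tp:g} hours"] = fmt(f) if f else ""
        rows.append(row)
    return pd.DataFrame(rows)
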