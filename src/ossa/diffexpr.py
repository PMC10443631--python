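"""Gap-split combinatorial differential expression, grouped Welch t-tests
with Benjamini-Hochberg, gene-set inflammation scores, and subgroup-relative
proportion correlation.

The gap-split test orders the regions (bones) by a gene's mean
log-normalized expression and splits the ordering at the largest gap
between consecutive means.  Two Welch t-tests are combined: one comparing
all cells of the high group against all cells of the low group, one
comparing only the two regions flanking the gap (this second test
guarantees the boundary itself is significant).  The final p-value is the
maximum of the two and the final log2 fold change the minimum, and a gene
is called differentially expressed at p < 0.05 and LFC > 1 (0.5 for the
neutrophil cross-compartment analysis).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedLayer, ResultTable
from ._utils import logger

_LFC_EPS = 1e-9

PRO_INFLAMMATORY_GENES = (
    "Il6", "Il1a", "Il1b", "Ifng", "Il11", "Il7d", "Il7f", "Il18", "Tnf",
)
ANTI_INFLAMMATORY_GENES = ("Il1rn", "Tgfb1", "Il4", "Il10", "Il12a", "Il13")


@dataclasses.dataclass
class DEThresholds:
    p_max: float = 0.05
    lfc_min: float = 1.0  # 0.5 for the neutrophil cross-compartment analysis

    def validate(self) -> "DEThresholds":
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must be in (0,1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        return self


NEUTROPHIL_THRESHOLDS = DEThresholds(p_max=0.05, lfc_min=0.5)


@dataclasses.dataclass
class GapSplitResult:
    gene_id: str
    cell_type: str
    ordered_regions: list
    split_index: int  # k* = size of the high group
    high_group: list
    low_group: list
    p_group: float
    p_boundary: float
    lfc_group: float
    lfc_boundary: float

    @property
    def p_final(self) -> float:
        return max(self.p_group, self.p_boundary)

    @property
    def lfc_final(self) -> float:
        return min(self.lfc_group, self.lfc_boundary)

    def is_deg(self, thresholds: DEThresholds) -> bool:
        return (self.p_final < thresholds.p_max) and (self.lfc_final > thresholds.lfc_min)

    def direction(self, region: str) -> str:
        return "up" if region in self.high_group else "down"


def _welch_from_stats(n1, m1, v1, n2, m2, v2):
    """Welch t-test p-value from group summary statistics (vectorized).

    Degenerate variance (both groups constant): p = 1 if the means agree,
    else 0."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        )
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    t = np.where(degenerate, 0.0, t)
    return t, p


def _lfc(a_mean: np.ndarray, b_mean: np.ndarray) -> np.ndarray:
    """log2 ratio of de-logged group means with a 1e-9 pseudocount."""
    return np.log2((a_mean + _LFC_EPS) / (b_mean + _LFC_EPS))


def _region_stats(values: sp.csr_matrix, regions: np.ndarray, region_list: list[str]):
    """Per-region per-gene n, sum, sum-of-squares (log values) and sum of
    expm1 values, in the given region order."""
    G = values.shape[1]
    R = len(region_list)
    n = np.zeros(R)
    s = np.zeros((R, G))
    ss = np.zeros((R, G))
    se = np.zeros((R, G))
    sq = values.multiply(values)
    ex = sp.csr_matrix(values, copy=True)
    ex.data = np.expm1(ex.data)
    for i, r in enumerate(region_list):
        mask = np.flatnonzero(regions == r)
        n[i] = len(mask)
        s[i] = np.asarray(values[mask].sum(axis=0)).ravel()
        ss[i] = np.asarray(sq[mask].sum(axis=0)).ravel()
        se[i] = np.asarray(ex[mask].sum(axis=0)).ravel()
    return n, s, ss, se


def _gap_split_core(n, s, ss, se, region_list):
    """Vectorized gap-split over all genes of one stratum.

    Parameters are per-region per-gene summary stats (counts, sums, sums of
    squares of the log values, sums of expm1 values); ``region_list`` must be
    lexicographically sorted so the stable ordering tie-breaks by name.
    Returns a dict of per-gene arrays.
    """
    R, G = s.shape
    means = s / n[:, None]
    order = np.argsort(-means, axis=0, kind="stable")  # descending, ties → lexicographic
    msort = np.take_along_axis(means, order, axis=0)
    gaps = msort[:-1] - msort[1:]
    kstar = gaps.argmax(axis=0) + 1  # size of high group, in 1..R-1
    if np.any(gaps.max(axis=0) == 0):
        logger.warning("gap-split: %d gene(s) with all-equal region means; k*=1 used",
                       int((gaps.max(axis=0) == 0).sum()))

    nsort = np.broadcast_to(n[:, None], (R, G))
    nsort = np.take_along_axis(nsort, order, axis=0)
    ssort = np.take_along_axis(s, order, axis=0)
    sssort = np.take_along_axis(ss, order, axis=0)
    sesort = np.take_along_axis(se, order, axis=0)

    cn = np.cumsum(nsort, axis=0)
    cs = np.cumsum(ssort, axis=0)
    css = np.cumsum(sssort, axis=0)
    cse = np.cumsum(sesort, axis=0)
    gi = np.arange(G)
    ki = kstar - 1
    nH = cn[ki, gi]
    nL = cn[-1, gi] - nH
    sH = cs[ki, gi]
    sL = cs[-1, gi] - sH
    ssH = css[ki, gi]
    ssL = css[-1, gi] - ssH
    seH = cse[ki, gi]
    seL = cse[-1, gi] - seH

    def var(nn, su, sq):
        m = su / nn
        return np.maximum((sq - nn * m**2) / np.maximum(nn - 1, 1), 0.0), m

    vH, mH = var(nH, sH, ssH)
    vL, mL = var(nL, sL, ssL)
    _, p_group = _welch_from_stats(nH, mH, vH, nL, mL, vL)
    lfc_group = _lfc(seH / nH, seL / nL)

    # boundary pair: ordered ranks k*-1 and k*
    nb1 = nsort[ki, gi]
    nb2 = nsort[kstar, gi]
    vb1, mb1 = var(nb1, ssort[ki, gi], sssort[ki, gi])
    vb2, mb2 = var(nb2, ssort[kstar, gi], sssort[kstar, gi])
    _, p_boundary = _welch_from_stats(nb1, mb1, vb1, nb2, mb2, vb2)
    lfc_boundary = _lfc(sesort[ki, gi] / nb1, sesort[kstar, gi] / nb2)

    region_arr = np.asarray(region_list)
    ordered = region_arr[order.T]  # G x R
    return {
        "order": ordered,
        "split_index": kstar,
        "p_group": p_group,
        "p_boundary": p_boundary,
        "lfc_group": lfc_group,
        "lfc_boundary": lfc_boundary,
    }


def _eligible_regions(regions: np.ndarray) -> list[str]:
    out = []
    for r in sorted(map(str, pd.unique(regions))):
        if (regions == r).sum() >= 2:
            out.append(r)
        else:
            logger.warning("region %s has < 2 cells; excluded from gap-split ordering", r)
    return out


def gap_split_test(
    layer: NormalizedLayer,
    region_labels: Sequence,
    gene_id: str,
    thresholds: DEThresholds | None = None,
    cell_type: str = "all",
) -> GapSplitResult:
    """The gap-split two-t-test procedure for a single gene."""
    regions = np.asarray(region_labels)
    pos = {g: i for i, g in enumerate(layer.gene_ids)}
    if gene_id not in pos:
        raise KeyError(f"gene {gene_id!r} not in layer")
    region_list = _eligible_regions(regions)
    if len(region_list) < 2:
        raise ValueError("need at least 2 regions with >= 2 cells")
    col = layer.values[:, [pos[gene_id]]]
    keep = np.isin(regions, region_list)
    n, s, ss, se = _region_stats(sp.csr_matrix(col[np.flatnonzero(keep)]), regions[keep], region_list)
    core = _gap_split_core(n, s, ss, se, region_list)
    k = int(core["split_index"][0])
    ordered = list(core["order"][0])
    return GapSplitResult(
        gene_id=gene_id,
        cell_type=cell_type,
        ordered_regions=ordered,
        split_index=k,
        high_group=ordered[:k],
        low_group=ordered[k:],
        p_group=float(core["p_group"][0]),
        p_boundary=float(core["p_boundary"][0]),
        lfc_group=float(core["lfc_group"][0]),
        lfc_boundary=float(core["lfc_boundary"][0]),
    )


def run_combinatorial_de(
    layer: NormalizedLayer,
    region_labels: Sequence,
    cell_type_labels: Sequence | None = None,
    thresholds: DEThresholds | None = None,
    scope: str = "per_cell_type",
) -> ResultTable:
    """Gap-split test for every gene within each cell-type stratum (or
    pooled).  All tested genes are retained with their ``is_deg`` flag; the
    per-region up/down counts follow by aggregation."""
    thresholds = (thresholds or DEThresholds()).validate()
    regions = np.asarray(region_labels)
    if scope == "pooled" or cell_type_labels is None:
        strata = {"all": np.arange(len(regions))}
    elif scope == "per_cell_type":
        cts = np.asarray(cell_type_labels)
        strata = {
            str(ct): np.flatnonzero(cts == ct)
            for ct in sorted(map(str, pd.unique(cts)))
        }
    else:
        raise ValueError(f"unknown scope {scope!r}")
    frames = []
    for ct, idx in strata.items():
        sub_regions = regions[idx]
        region_list = _eligible_regions(sub_regions)
        if len(region_list) < 2:
            logger.warning("stratum %s has < 2 usable regions; skipped", ct)
            continue
        keep = idx[np.isin(sub_regions, region_list)]
        vals = sp.csr_matrix(layer.values[keep])
        n, s, ss, se = _region_stats(vals, regions[keep], region_list)
        core = _gap_split_core(n, s, ss, se, region_list)
        p_final = np.maximum(core["p_group"], core["p_boundary"])
        lfc_final = np.minimum(core["lfc_group"], core["lfc_boundary"])
        k = core["split_index"]
        high = [",".join(core["order"][g][: k[g]]) for g in range(len(k))]
        low = [",".join(core["order"][g][k[g]:]) for g in range(len(k))]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": layer.gene_ids,
                    "cell_type": ct,
                    "ordered_regions": [",".join(o) for o in core["order"]],
                    "split_index": k,
                    "high_group": high,
                    "low_group": low,
                    "p_group": core["p_group"],
                    "p_boundary": core["p_boundary"],
                    "lfc_group": core["lfc_group"],
                    "lfc_boundary": core["lfc_boundary"],
                    "p_final": p_final,
                    "lfc_final": lfc_final,
                    "is_deg": (p_final < thresholds.p_max) & (lfc_final > thresholds.lfc_min),
                }
            )
        )
    if not frames:
        raise ValueError("no stratum with >= 2 usable regions")
    table = pd.concat(frames, ignore_index=True)
    return ResultTable(table, key_columns=("cell_type", "gene_id"))


def region_deg_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region counts of genes called up (region in the high group) and
    down, aggregated over strata — the stacked-bar summary."""
    rows = []
    for _, r in table[table["is_deg"]].iterrows():
        high = set(r["high_group"].split(","))
        for region in r["ordered_regions"].split(","):
            rows.append({"region": region, "direction": "up" if region in high else "down"})
    if not rows:
        return pd.DataFrame(columns=["region", "up", "down"])
    df = pd.DataFrame(rows)
    out = df.value_counts(["region", "direction"]).unstack(fill_value=0)
    return out.reset_index().rename_axis(None, axis=1)


def grouped_ttest_bh(
    layer: NormalizedLayer,
    cell_mask: Sequence[bool],
    gene_list: Sequence[str],
    group_labels: Sequence,
    group_a: str,
    group_b: str,
) -> ResultTable:
    """Per-gene Welch t-tests between two groups within a cell mask, with
    Benjamini-Hochberg adjustment over the listed genes only."""
    mask = np.asarray(cell_mask, dtype=bool)
    labels = np.asarray(group_labels)
    ia = np.flatnonzero(mask & (labels == group_a))
    ib = np.flatnonzero(mask & (labels == group_b))
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need >= 2 cells")
    pos = {g: i for i, g in enumerate(layer.gene_ids)}
    rows = []
    for gene in gene_list:
        if gene not in pos:
            logger.warning("gene %s absent from the layer; NA row emitted", gene)
            rows.append(
                {"gene_id": gene, "group_a": group_a, "group_b": group_b,
                 "t": np.nan, "p_raw": np.nan, "lfc": np.nan}
            )
            continue
        col = np.asarray(layer.values[:, pos[gene]].todense()).ravel()
        a, b = col[ia], col[ib]
        t, p = _welch_from_stats(
            len(a), a.mean(), a.var(ddof=1), len(b), b.mean(), b.var(ddof=1)
        )
        lfc = float(_lfc(np.expm1(a).mean(), np.expm1(b).mean()))
        rows.append(
            {"gene_id": gene, "group_a": group_a, "group_b": group_b,
             "t": float(t), "p_raw": float(p), "lfc": lfc}
        )
    frame = pd.DataFrame(rows)
    tested = frame["p_raw"].notna()
    adj = np.full(len(frame), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = multipletests(
            frame.loc[tested, "p_raw"], method="fdr_bh"
        )[1]
    frame["p_adj"] = adj
    return ResultTable(frame, key_columns=("gene_id",))


@dataclasses.dataclass
class GeneSetScore:
    set_name: str
    genes: list
    per_cell: np.ndarray
    group_stats: pd.DataFrame  # group, mean, sd, n


def gene_set_score(
    layer: NormalizedLayer,
    set_name: str,
    gene_list: Sequence[str],
    group_labels: Sequence,
) -> GeneSetScore:
    """Per-cell mean log-normalized expression over a gene set, summarized
    (mean ± SD) per group.  Genes absent from the matrix are dropped with a
    warning, never imputed."""
    pos = {g: i for i, g in enumerate(layer.gene_ids)}
    present = [g for g in gene_list if g in pos]
    missing = [g for g in gene_list if g not in pos]
    if missing:
        logger.warning("gene set %s: %d gene(s) absent and dropped: %s",
                       set_name, len(missing), ", ".join(missing))
    if not present:
        raise ValueError(f"no gene of set {set_name!r} present in the matrix")
    idx = [pos[g] for g in present]
    sub = np.asarray(layer.values[:, idx].todense())
    per_cell = sub.mean(axis=1)
    labels = np.asarray(group_labels)
    rows = []
    for g in sorted(map(str, pd.unique(labels))):
        v = per_cell[labels == g]
        rows.append(
            {"group": g, "mean": float(v.mean()),
             "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0, "n": len(v)}
        )
    return GeneSetScore(
        set_name=set_name, genes=present, per_cell=per_cell,
        group_stats=pd.DataFrame(rows),
    )


def proportion_correlation(
    sc_counts: pd.DataFrame,
    ref_props: pd.DataFrame,
    parent_map: Mapping[str, str],
) -> pd.DataFrame:
    """Correlate cell-type proportions with a reference measured relative to
    gated subgroups (as in flow cytometry).

    ``sc_counts``: samples × cell types, raw cell counts.  Each type's
    proportion is computed relative to the total of the types sharing its
    parent gate; per-sample Pearson r against the reference is reported with
    the mean over samples appended.
    """
    types = [t for t in sc_counts.columns if t in parent_map]
    if not types:
        raise ValueError("no shared cell types after parent mapping")
    rel = pd.DataFrame(index=sc_counts.index, columns=types, dtype=float)
    for t in types:
        siblings = [u for u in types if parent_map[u] == parent_map[t]]
        denom = sc_counts[siblings].sum(axis=1)
        rel[t] = np.where(denom > 0, sc_counts[t] / denom.replace(0, np.nan), np.nan)
    rows = []
    for sample in sc_counts.index:
        a = rel.loc[sample, types].astype(float)
        b = ref_props.loc[sample, types].astype(float)
        ok = a.notna() & b.notna()
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        rows.append({"sample": sample, "pearson_r": r, "n_types": int(ok.sum())})
    out = pd.DataFrame(rows)
    mean_r = out["pearson_r"].mean()
    out = pd.concat(
        [out, pd.DataFrame([{"sample": "__mean__", "pearson_r": mean_r,
                             "n_types": int(out["n_types"].sum())}])],
        ignore_index=True,
    )
    return out


class GapSplitDE:
    """Model-style interface for the combinatorial DE test.

    ``GapSplitDE(layer, regions, cell_types).fit()`` runs the gap-split test
    for every gene in every cell-type stratum and returns results holding
    the full per-gene table, the DEG calls, and per-region up/down counts.
    """

    def __init__(
        self,
        layer: NormalizedLayer,
        region_labels: Sequence,
        cell_type_labels: Sequence | None = None,
        thresholds: DEThresholds | None = None,
        scope: str = "per_cell_type",
    ):
        self.layer = layer
        self.regions = region_labels
        self.cell_types = cell_type_labels
        self.thresholds = (thresholds or DEThresholds()).validate()
        self.scope = scope

    def fit(self) -> "GapSplitDEResults":
        table = run_combinatorial_de(
            self.layer, self.regions, self.cell_types, self.thresholds, self.scope
        )
        return GapSplitDEResults(table, self.thresholds)


class GapSplitDEResults:
    def __init__(self, table: ResultTable, thresholds: DEThresholds):
        self.result_table = table
        self.table = table.frame
        self.thresholds = thresholds

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_deg"]]

    def region_counts(self) -> pd.DataFrame:
        return region_deg_counts(self.table)

    def summary(self) -> str:
        counts = self.region_counts()
        lines = [
            "Gap-split combinatorial DE",
            "=" * 26,
            f"genes tested: {self.table['gene_id'].nunique()}  "
            f"strata: {self.table['cell_type'].nunique()}  "
            f"DEG calls: {int(self.table['is_deg'].sum())} "
            f"(p < {self.thresholds.p_max:g}, LFC > {self.thresholds.lfc_min:g})",
        ]
        for _, row in counts.iterrows():
            up = int(row.get("up", 0))
            down = int(row.get("down", 0))
            lines.append(f"  {row['region']:>12s}: {up} up / {down} down")
        return "\n".join(lines)

    def plot_counts(self, ax=None):
        import matplotlib.pyplot as plt

        counts = self.region_counts()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        if counts.empty:
            ax.set_title("no DEG calls")
            return ax
        regions = counts["region"]
        up = counts.get("up", pd.Series(0, index=counts.index))
        down = counts.get("down", pd.Series(0, index=counts.index))
        ax.bar(regions, up, label="up", color="#c0392b")
        ax.bar(regions, -down, label="down", color="#2980b9")
        ax.axhline(0, color="black", lw=0.5)
        ax.set_ylabel("DEGs")
        ax.legend()
        return ax
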