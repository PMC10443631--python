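"""Balanced-sampling ligand-receptor permutation analysis with per-region
uniqueness calls.

An interaction is the tuple (ligand, receptor, sender cell type, receiver
cell type) evaluated within one region.  Only cell types with at least 10
cells in every region enter the analysis.  Within a region, every eligible
cell type is resampled to exactly 400 cells (down-sampling without
replacement, up-sampling with replacement) so the permutation null is not
skewed toward abundant types.  The interaction score is the average of the
ligand's mean log-normalized expression over sender cells and the
receptor's mean over receiver cells; pairs where either partner is
expressed in under 10% of its cells are inexpressible and skipped.  The
null shuffles the cell-type labels of the balanced sample jointly — one
shuffle per permutation shared by every interaction of the region — and an
interaction is significant only when no permutation reaches the observed
score (p = 0 at 1000 permutations).  An interaction is unique to a region
when it is significant there and its p-value in every other region exceeds
0.95; it is common when significant in every region.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, NormalizedLayer, ResultTable
from ._utils import logger

MIN_EXPRESSING_FRACTION = 0.1


@dataclasses.dataclass
class LRDatabase:
    """Ligand-receptor pair catalog.  Complex partners may be written as
    ``GeneA+GeneB``; the member with the minimum per-type mean represents
    the complex."""

    table: pd.DataFrame  # interaction_id, ligand, receptor

    def __post_init__(self):
        t = self.table
        for col in ("interaction_id", "ligand", "receptor"):
            if col not in t.columns:
                raise ValueError(f"LR database missing column {col!r}")
            if (t[col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty values in LR database column {col!r}")
        if t["interaction_id"].duplicated().any():
            raise ValueError("duplicate interaction ids in LR database")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "LRDatabase":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def bundled_toy(cls) -> "LRDatabase":
        """The bundled ~50-pair toy database (includes Pecam1-Cd177,
        Cd74-Mif, Il1b-Adrb2, Ccl4-Ccr5, Cxcl2-Dpp4, Cd28-Cd86)."""
        ref = importlib.resources.files("ossa.data").joinpath("lr_toy_db.tsv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def eligible_cell_types(
    cohort: CellMatrix, regions: Sequence[str], min_cells: int = 10
) -> list[str]:
    """Cell types with at least ``min_cells`` cells in every listed region."""
    if not len(regions):
        raise ValueError("regions must be non-empty")
    cells = cohort.cells
    out = []
    for ct in sorted(map(str, cells["cell_type"].unique())):
        ok = all(
            ((cells["cell_type"] == ct) & (cells["region"] == r)).sum() >= min_cells
            for r in regions
        )
        if ok:
            out.append(ct)
    return out


def balanced_sample(
    cell_indices: np.ndarray,
    cell_types: Sequence[str],
    types: Sequence[str],
    target_n: int = 400,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resample every listed type to exactly ``target_n`` cells.

    Types above the target are down-sampled uniformly without replacement
    (a uniform stand-in for sketching the background distribution); types
    below are up-sampled with replacement; exact matches pass through.
    Returns ``target_n × len(types)`` indices into the original cohort.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cell_indices = np.asarray(cell_indices)
    cell_types = np.asarray(cell_types)
    picked = []
    for t in types:
        members = cell_indices[cell_types == t]
        if len(members) == 0:
            raise ValueError(f"cell type {t!r} has no cells to sample")
        if len(members) > target_n:
            picked.append(rng.choice(members, size=target_n, replace=False))
        elif len(members) < target_n:
            picked.append(rng.choice(members, size=target_n, replace=True))
        else:
            picked.append(members.copy())
    return np.concatenate(picked)


def interaction_score(
    type_means: Mapping[str, np.ndarray] | pd.DataFrame,
    type_fractions: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
) -> tuple[float, float, float]:
    """(μ, ligand fraction, receptor fraction) from per-type gene means and
    expressing fractions.  μ = (mean_ligand|sender + mean_receptor|receiver)/2;
    complexes ('A+B') take the minimum member."""
    mu_l = _partner_value(type_means, ligand, sender)
    mu_r = _partner_value(type_means, receptor, receiver)
    fr_l = _partner_value(type_fractions, ligand, sender)
    fr_r = _partner_value(type_fractions, receptor, receiver)
    return (mu_l + mu_r) / 2.0, fr_l, fr_r


def _partner_value(table: pd.DataFrame, gene: str, cell_type: str) -> float:
    members = gene.split("+")
    return float(min(table.loc[cell_type, m] for m in members))


def _dense_expr(layer: NormalizedLayer, genes: list[str]) -> tuple[np.ndarray, dict]:
    pos = {g: i for i, g in enumerate(layer.gene_ids)}
    idx = [pos[g] for g in genes]
    dense = np.asarray(layer.values[:, idx].todense(), dtype=np.float64)
    return dense, {g: j for j, g in enumerate(genes)}


def _db_genes(db: LRDatabase) -> tuple[list[str], list[str]]:
    """(present-interaction member genes, flattened unique gene list)."""
    genes = []
    for col in ("ligand", "receptor"):
        for entry in db.table[col]:
            genes.extend(str(entry).split("+"))
    return sorted(set(genes))


def analyze_region(
    layer: NormalizedLayer,
    region_cell_idx: np.ndarray,
    cell_type_labels: Sequence[str],
    db: LRDatabase,
    types: Sequence[str],
    region: str = "region",
    target_n: int = 400,
    n_perm: int = 1000,
    min_fraction: float = MIN_EXPRESSING_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """All (interaction, sender, receiver) permutation tests of one region.

    One balanced sample is drawn, then ``n_perm`` joint shuffles of its
    cell-type labels are shared by every interaction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    types = list(types)
    rng = np.random.default_rng(seed)
    idx = balanced_sample(
        np.asarray(region_cell_idx),
        np.asarray(cell_type_labels)[np.asarray(region_cell_idx)],
        types,
        target_n=target_n,
        rng=rng,
    )
    all_genes = _db_genes(db)
    present = [g for g in all_genes if g in set(layer.gene_ids)]
    missing = sorted(set(all_genes) - set(present))
    if missing:
        logger.warning(
            "region %s: %d LR gene(s) absent from the matrix; their "
            "interactions are skipped: %s", region, len(missing), ", ".join(missing)
        )
    expr, gcol = _dense_expr(layer, present)
    expr = expr[idx]  # balanced sample rows, type blocks of size target_n
    n_bal = expr.shape[0]
    labels = np.repeat(np.arange(len(types)), target_n)

    def group_means(lab: np.ndarray) -> np.ndarray:
        out = np.empty((len(types), expr.shape[1]))
        for t in range(len(types)):
            out[t] = expr[lab == t].mean(axis=0)
        return out

    obs_means = pd.DataFrame(group_means(labels), index=types, columns=present)
    fractions = pd.DataFrame(
        np.vstack([(expr[labels == t] > 0).mean(axis=0) for t in range(len(types))]),
        index=types, columns=present,
    )

    # enumerate testable interactions
    rows = []
    mu_obs_list = []
    indexers = []  # (ligand member cols, sender, receptor member cols, receiver)
    for _, dbrow in db.table.iterrows():
        lig, rec = str(dbrow["ligand"]), str(dbrow["receptor"])
        members_ok = all(m in gcol for m in lig.split("+")) and all(
            m in gcol for m in rec.split("+")
        )
        for si, sender in enumerate(types):
            for ri, receiver in enumerate(types):
                row = {
                    "interaction_id": dbrow["interaction_id"],
                    "ligand": lig,
                    "receptor": rec,
                    "sender": sender,
                    "receiver": receiver,
                    "region": region,
                }
                if not members_ok:
                    row.update(mu=np.nan, frac_ligand=np.nan, frac_receptor=np.nan,
                               tested=False, n_perm=n_perm, k=-1, p=np.nan,
                               significant=False)
                    rows.append(row)
                    continue
                mu, fl, fr = interaction_score(
                    obs_means, fractions, lig, rec, sender, receiver
                )
                tested = (fl >= min_fraction) and (fr >= min_fraction)
                row.update(mu=mu, frac_ligand=fl, frac_receptor=fr, tested=tested,
                           n_perm=n_perm, k=-1, p=np.nan, significant=False)
                rows.append(row)
                if tested:
                    mu_obs_list.append(mu)
                    indexers.append(
                        (
                            [gcol[m] for m in lig.split("+")], si,
                            [gcol[m] for m in rec.split("+")], ri,
                            len(rows) - 1,
                        )
                    )

    if indexers:
        mu_obs = np.asarray(mu_obs_list)
        k = np.zeros(len(indexers), dtype=np.int64)
        for _ in range(n_perm):
            perm = labels[rng.permutation(n_bal)]
            means = group_means(perm)
            mu_perm = np.empty(len(indexers))
            for j, (lc, si, rc, ri, _) in enumerate(indexers):
                ml = means[si, lc].min()
                mr = means[ri, rc].min()
                mu_perm[j] = (ml + mr) / 2.0
            k += mu_perm >= mu_obs
        for j, (_, _, _, _, row_i) in enumerate(indexers):
            rows[row_i]["k"] = int(k[j])
            rows[row_i]["p"] = k[j] / n_perm
            rows[row_i]["significant"] = bool(k[j] == 0)
    return pd.DataFrame(rows)


def permutation_p(
    layer: NormalizedLayer,
    region_cell_idx: np.ndarray,
    cell_type_labels: Sequence[str],
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    types: Sequence[str] | None = None,
    target_n: int = 400,
    n_perm: int = 1000,
    seed: int = 0,
    min_fraction: float = MIN_EXPRESSING_FRACTION,
) -> pd.Series:
    """Single-interaction convenience wrapper around :func:`analyze_region`."""
    if types is None:
        labs = np.asarray(cell_type_labels)[np.asarray(region_cell_idx)]
        types = sorted(map(str, pd.unique(labs)))
    db = LRDatabase(
        pd.DataFrame(
            [{"interaction_id": f"{ligand}_{receptor}", "ligand": ligand, "receptor": receptor}]
        )
    )
    out = analyze_region(
        layer, region_cell_idx, cell_type_labels, db, types,
        target_n=target_n, n_perm=n_perm, seed=seed, min_fraction=min_fraction,
    )
    hit = out[(out["sender"] == sender) & (out["receiver"] == receiver)]
    return hit.iloc[0]


def call_common_and_unique(
    region_tables: Mapping[str, pd.DataFrame],
    delta_min: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-region common and unique interaction calls.

    Untested interactions count as p = 1 (logged).  Common: p = 0 in every
    region.  Unique to r: p = 0 in r and p > ``delta_min`` in every other
    region (Δp strictly above the threshold).
    """
    if not (0.0 < delta_min < 1.0):
        raise ValueError("delta_min must be in (0,1)")
    regions = sorted(region_tables)
    key = ["interaction_id", "sender", "receiver"]
    pmat = {}
    for r in regions:
        t = region_tables[r]
        p = t.set_index(key)["p"]
        pmat[r] = p
    universe = sorted(set().union(*[set(v.index) for v in pmat.values()]))
    P = pd.DataFrame(index=pd.MultiIndex.from_tuples(universe, names=key), columns=regions, dtype=float)
    for r in regions:
        P[r] = pmat[r].reindex(P.index)
    n_untested = int(P.isna().sum().sum())
    if n_untested:
        logger.info("%d (interaction, region) entries untested; treated as p = 1", n_untested)
    P = P.fillna(1.0)

    common = P[(P == 0).all(axis=1)].reset_index()[key]
    unique_rows = []
    for r in regions:
        others = [o for o in regions if o != r]
        sig_here = P[r] == 0
        if others:
            delta = P[others].min(axis=1)  # Δp = min over others of p(other) − 0
            supported = sig_here & (delta > delta_min)
        else:
            delta = pd.Series(np.nan, index=P.index)
            supported = sig_here
        for tup in P.index[sig_here]:
            unique_rows.append(
                {
                    "interaction_id": tup[0], "sender": tup[1], "receiver": tup[2],
                    "unique_region": r,
                    "delta_p": float(delta.loc[tup]) if others else np.nan,
                    "supported": bool(supported.loc[tup]),
                }
            )
    unique = pd.DataFrame(
        unique_rows,
        columns=["interaction_id", "sender", "receiver", "unique_region", "delta_p", "supported"],
    )
    return common, unique


class LRPermutationModel:
    """Model-style interface: ligand-receptor permutation analysis over all
    regions of a cohort.

    ``fit(n_perm, seed)`` runs :func:`analyze_region` per region (eligible
    cell types determined cohort-wide) and derives the cross-region common
    and unique calls.
    """

    def __init__(
        self,
        cohort: CellMatrix,
        layer: NormalizedLayer,
        db: LRDatabase | None = None,
        regions: Sequence[str] | None = None,
        min_cells: int = 10,
        target_n: int = 400,
        delta_min: float = 0.95,
        min_fraction: float = MIN_EXPRESSING_FRACTION,
    ):
        self.cohort = cohort
        self.layer = layer
        self.db = db if db is not None else LRDatabase.bundled_toy()
        if regions is None:
            regions = sorted(map(str, cohort.cells["region"].unique()))
        self.regions = list(regions)
        self.min_cells = min_cells
        self.target_n = target_n
        self.delta_min = delta_min
        self.min_fraction = min_fraction

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "LRResults":
        types = eligible_cell_types(self.cohort, self.regions, self.min_cells)
        if not types:
            raise ValueError(
                f"no cell type has >= {self.min_cells} cells in every region"
            )
        region_col = self.cohort.cells["region"].to_numpy()
        ct_col = self.cohort.cells["cell_type"].to_numpy()
        tables = {}
        for i, r in enumerate(self.regions):
            idx = np.flatnonzero(region_col == r)
            tables[r] = analyze_region(
                self.layer, idx, ct_col, self.db, types,
                region=r, target_n=self.target_n, n_perm=n_perm,
                min_fraction=self.min_fraction,
                seed=int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % 2**31),
            )
        common, unique = call_common_and_unique(tables, self.delta_min)
        return LRResults(tables, common, unique, types, self.delta_min)


class LRResults:
    def __init__(self, tables, common, unique, cell_types, delta_min):
        self.region_tables = tables
        self.common = common
        self.unique = unique
        self.cell_types = cell_types
        self.delta_min = delta_min
        self.table = pd.concat(tables.values(), ignore_index=True)

    def to_result_table(self) -> ResultTable:
        return ResultTable(
            self.table,
            key_columns=("region", "interaction_id", "sender", "receiver"),
        )

    def supported_unique(self) -> pd.DataFrame:
        return self.unique[self.unique["supported"]]

    def summary(self) -> str:
        sig = self.table[self.table["significant"]]
        lines = [
            "Ligand-receptor permutation analysis",
            "=" * 36,
            f"regions: {len(self.region_tables)}  eligible cell types: {len(self.cell_types)}",
            f"tested interactions: {int(self.table['tested'].sum())}  "
            f"significant (p = 0): {len(sig)}",
            f"common to all regions: {len(self.common)}",
            f"supported unique calls (Δp > {self.delta_min:g}): "
            f"{len(self.supported_unique())}",
        ]
        for r, t in self.region_tables.items():
            lines.append(f"  {r:>12s}: {int(t['significant'].sum())} significant")
        return "\n".join(lines)
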