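"""Consensus ranking of interface mutations from multiple ddG predictors.

An alanine scan of interfacial residues is scored by several independent
predictors for two quantities per mutation: the change in binding free
energy of the heterodimer (ddG_binding, kcal/mol; positive = weaker binding)
and the change in folding free energy of the mutated monomer (ddG_folding).
The pipeline is:

1. average each quantity over available predictors;
2. exclude mutations whose averaged |ddG_folding| exceeds a stability
   threshold (default 0.5 kcal/mol) — a mutation that destabilises the
   monomer would confound the binding readout;
3. within each binding predictor, rank the *retained* mutations by
   descending ddG_binding (rank 1 = most disruptive), ties receiving
   fractional (mean) ranks;
4. average the per-predictor ranks and order by that mean rank.

The consensus order is deliberately not the order of averaged ddG_binding:
a mutation consistently near the top for every predictor beats one with a
single extreme value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MutationPrediction",
    "ConsensusRecord",
    "load_predictions",
    "load_table1_fixture",
    "average_ddg",
    "stability_filter",
    "consensus_rank",
    "emit_consensus_table",
]

DEFAULT_STABILITY_THRESHOLD = 0.5  # kcal/mol on averaged |ddG_folding|
DEFAULT_MIN_PREDICTORS = 4

FoldingMode = Literal["abs_of_mean", "mean_of_abs"]

_ID_COLS = ["subunit", "position", "wt", "mut"]


@dataclass(frozen=True)
class MutationPrediction:
    """Per-predictor ddG values for a single point mutation."""

    subunit: str
    position: int
    wt_residue: str
    mut_residue: str
    binding_by_predictor: Mapping[str, float]
    folding_by_predictor: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"{self.label}: wild-type equals mutant residue")
        if not self.binding_by_predictor or not self.folding_by_predictor:
            raise ValueError(f"{self.label}: empty predictor map")

    @property
    def label(self) -> str:
        return f"{self.subunit}:{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass(frozen=True)
class ConsensusRecord:
    subunit: str
    position: int
    wt_residue: str
    mut_residue: str
    avg_ddg_binding: float
    avg_abs_ddg_folding: float
    binding_rank_by_predictor: Mapping[str, float]
    mean_rank: float
    final_rank: int
    retained: bool = True

    @property
    def label(self) -> str:
        return f"{self.subunit}:{self.wt_residue}{self.position}{self.mut_residue}"


def _read_table(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    p = Path(path_or_df)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(p, sep=sep)


def _to_long(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Accept long (..., predictor, value) or wide (one column per predictor)."""
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in _ID_COLS if c not in cols]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")
    df = df.rename(columns={cols[k]: k for k in cols})
    if "predictor" in df.columns and "value" in df.columns:
        long = df[_ID_COLS + ["predictor", "value"]].copy()
    else:
        pred_cols = [c for c in df.columns if c not in _ID_COLS]
        if not pred_cols:
            raise ValueError(f"{what} table has no predictor columns")
        long = df.melt(
            id_vars=_ID_COLS, value_vars=pred_cols,
            var_name="predictor", value_name="value",
        )
    long = long.dropna(subset=["value"])
    long["position"] = long["position"].astype(int)
    dup = long.duplicated(subset=_ID_COLS + ["predictor"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in long.index[dup]]  # 1-based incl. header
        raise ValueError(
            f"duplicate (mutation, predictor) pairs in {what} table at "
            f"file rows {rows}"
        )
    return long


def load_predictions(
    binding_table: str | Path | pd.DataFrame,
    folding_table: str | Path | pd.DataFrame,
    min_predictors: int = DEFAULT_MIN_PREDICTORS,
) -> list[MutationPrediction]:
    """Read binding and folding ddG tables (CSV/TSV, long or wide format).

    A mutation present with fewer than ``min_predictors`` values in either
    table is dropped with a warning — predictor webservers fail routinely
    and a mean over too few methods is not comparable with the rest.
    """
    b = _to_long(_read_table(binding_table), "binding")
    f = _to_long(_read_table(folding_table), "folding")
    preds: list[MutationPrediction] = []
    b_groups = {k: g for k, g in b.groupby(_ID_COLS)}
    f_groups = {k: g for k, g in f.groupby(_ID_COLS)}
    for key in sorted(set(b_groups) | set(f_groups)):
        bg = b_groups.get(key)
        fg = f_groups.get(key)
        n_b = 0 if bg is None else len(bg)
        n_f = 0 if fg is None else len(fg)
        if n_b < min_predictors or n_f < min_predictors:
            warnings.warn(
                f"mutation {key[0]}:{key[2]}{key[1]}{key[3]} has "
                f"{n_b} binding / {n_f} folding predictions "
                f"(< {min_predictors}); dropped",
                stacklevel=2,
            )
            continue
        preds.append(
            MutationPrediction(
                subunit=str(key[0]),
                position=int(key[1]),
                wt_residue=str(key[2]),
                mut_residue=str(key[3]),
                binding_by_predictor=dict(zip(bg["predictor"], bg["value"])),
                folding_by_predictor=dict(zip(fg["predictor"], fg["value"])),
            )
        )
    return preds


def average_ddg(
    m: MutationPrediction, folding_mode: FoldingMode = "abs_of_mean"
) -> tuple[float, float]:
    """(avg ddG_binding, averaged |ddG_folding|) over available predictors.

    ``folding_mode='abs_of_mean'`` (default) takes the absolute value of the
    mean folding ddG; ``'mean_of_abs'`` averages the absolute values.  The
    two differ when predictors disagree on sign.
    """
    b = np.mean(list(m.binding_by_predictor.values()))
    f_vals = np.asarray(list(m.folding_by_predictor.values()), dtype=float)
    if folding_mode == "abs_of_mean":
        f = abs(f_vals.mean())
    elif folding_mode == "mean_of_abs":
        f = np.abs(f_vals).mean()
    else:
        raise ValueError(f"unknown folding_mode {folding_mode!r}")
    return float(b), float(f)


def stability_filter(
    records: pd.DataFrame | Sequence[MutationPrediction],
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
    folding_mode: FoldingMode = "abs_of_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split mutations into (retained, excluded) by folding stability.

    A mutation is retained iff its averaged |ddG_folding| <= ``threshold``
    (strictly greater is excluded).  Accepts either a list of
    :class:`MutationPrediction` or any DataFrame with an
    ``avg_abs_ddg_folding`` column (e.g. the packaged consensus fixture).
    The excluded frame carries a ``reason`` column.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "avg_abs_ddg_folding" not in df.columns:
            raise ValueError("DataFrame lacks avg_abs_ddg_folding column")
    else:
        rows = []
        for m in records:
            b, f = average_ddg(m, folding_mode)
            rows.append(
                {
                    "subunit": m.subunit,
                    "position": m.position,
                    "wt": m.wt_residue,
                    "mut": m.mut_residue,
                    "avg_ddg_binding": b,
                    "avg_abs_ddg_folding": f,
                }
            )
        df = pd.DataFrame(rows)
    keep = df["avg_abs_ddg_folding"] <= threshold
    excluded = df[~keep].copy()
    excluded["reason"] = [
        f"avg |ddG_folding| {v:.3f} > {threshold} kcal/mol"
        for v in excluded["avg_abs_ddg_folding"]
    ]
    return df[keep].copy(), excluded


def consensus_rank(
    retained: Sequence[MutationPrediction],
    folding_mode: FoldingMode = "abs_of_mean",
) -> list[ConsensusRecord]:
    """Rank-average consensus over the retained mutations.

    Within each predictor, mutations are ranked by descending ddG_binding
    (rank 1 = most binding-disruptive), ties averaged fractionally; a
    predictor only ranks the mutations it scored.  Mutations are then
    ordered by ascending mean rank; ties broken by larger averaged
    ddG_binding, then by (subunit, position) for determinism.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("no retained mutations to rank")
    predictors = sorted({p for m in retained for p in m.binding_by_predictor})
    ranks_by_mut: list[dict[str, float]] = [{} for _ in retained]
    for p in predictors:
        idx = [i for i, m in enumerate(retained) if p in m.binding_by_predictor]
        vals = np.array(
            [retained[i].binding_by_predictor[p] for i in idx], dtype=float
        )
        # descending: largest ddG_binding gets rank 1
        r = rankdata(-vals, method="average")
        for i, rank in zip(idx, r):
            ranks_by_mut[i][p] = float(rank)
    out = []
    for m, ranks in zip(retained, ranks_by_mut):
        b, f = average_ddg(m, folding_mode)
        out.append((m, b, f, ranks, float(np.mean(list(ranks.values())))))
    out.sort(key=lambda t: (t[4], -t[1], t[0].subunit, t[0].position))
    return [
        ConsensusRecord(
            subunit=m.subunit,
            position=m.position,
            wt_residue=m.wt_residue,
            mut_residue=m.mut_residue,
            avg_ddg_binding=b,
            avg_abs_ddg_folding=f,
            binding_rank_by_predictor=ranks,
            mean_rank=mean_rank,
            final_rank=i + 1,
        )
        for i, (m, b, f, ranks, mean_rank) in enumerate(out)
    ]


def emit_consensus_table(
    records: Sequence[ConsensusRecord] | pd.DataFrame, k: int | None = None
) -> pd.DataFrame:
    """Top-``k`` consensus rows as a DataFrame (all rows when k is None/large)."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "final_rank": [r.final_rank for r in records],
                "subunit": [r.subunit for r in records],
                "position": [r.position for r in records],
                "wt_residue": [r.wt_residue for r in records],
                "mut_residue": [r.mut_residue for r in records],
                "avg_abs_ddg_folding": [r.avg_abs_ddg_folding for r in records],
                "avg_ddg_binding": [r.avg_ddg_binding for r in records],
            }
        )
    if k is not None:
        if k < 0:
            raise ValueError("k must be >= 0")
        df = df.sort_values("final_rank").head(k)
    return df.reset_index(drop=True)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 20-row consensus table for the calpain-2 heterodimer.

    Averaged values and final ranks for the top 20 alanine-scan mutations at
    CAPN2/CAPNS1 interfacial residues, as published for the human calpain-2
    crystal structure.  Columns: final_rank, subunit, position, wt_residue,
    avg_abs_ddg_folding, avg_ddg_binding (kcal/mol).
    """
    with resources.files("calpain_ppi.data").joinpath(
        "table1_calpain2.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["mut_residue"] = "A"
    return df
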