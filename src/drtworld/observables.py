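"""Census of protocell classes and molecular species; time-series I/O and
competition outcome calls.

Protocells are classified by their exact gene-content signature (a cell
carrying both MSPG and NSR counts only in the joint class).  Gene counts
are sense-strand motif copies over the whole system; peptide counts sum
free, membrane-embedded and RNA-bound copies.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .config import GENE_LABELS, SequenceDefs
from .world import World, pair_index

#: Named protocell classes reported as columns (anything else is C_other).
_CLASS_COLUMNS = {
    frozenset(): "C_empty",
    frozenset({"MSPG"}): "C_mspg",
    frozenset({"CTPG"}): "C_ctpg",
    frozenset({"NSR"}): "C_nsr",
    frozenset({"CTR"}): "C_ctr",
    frozenset({"NSPG"}): "C_nspg",
    frozenset({"MSPG", "NSR"}): "C_mspg_nsr",
    frozenset({"MSPG", "NSPG"}): "C_mspg_nspg",
}

CENSUS_COLUMNS = (
    ["step", "cells"]
    + list(_CLASS_COLUMNS.values()) + ["C_other"]
    + ["mspg", "nspg", "ctpg", "nsr", "ctr"]
    + ["msp", "nsp", "ctp"]
    + ["npre", "apre", "aapre", "nt", "am_free", "am_membrane", "aa",
       "rna_strands", "rna_residues", "peptides_free"]
)


def take_census(world: World) -> dict:
    """Deterministic full scan of the world (pure function of state)."""
    from .rna import strand_labels

    defs = world.seq_defs
    row = {k: 0 for k in CENSUS_COLUMNS}
    row["step"] = world.step_count

    gene_counts = {g: 0 for g in GENE_LABELS}
    room_labels: Dict[Tuple[int, int], set] = {}
    bound_pairs = {defs.msp_pair: 0, defs.nsp_pair: 0, defs.control_pair: 0}
    n_strands = 0
    n_residues = 0
    for room, lst in world.strands.items():
        labels = set()
        for s in lst:
            n_strands += 1
            n_residues += s.residues
            sl = strand_labels(s, defs)
            labels |= sl
            for g in sl:
                gene_counts[g] += 1
            for cargo in s.bound.values():
                if len(cargo) == 2 and cargo in bound_pairs:
                    bound_pairs[cargo] += 1
        if labels:
            room_labels[room] = labels

    class_counts: Dict[frozenset, int] = {}
    for room in world.cells:
        sig = frozenset(room_labels.get(room, set()))
        class_counts[sig] = class_counts.get(sig, 0) + 1
    row["cells"] = len(world.cells)
    for sig, count in class_counts.items():
        row[_CLASS_COLUMNS.get(sig, "C_other")] += count

    for g in GENE_LABELS:
        row[g.lower()] = gene_counts[g]

    msp_i = pair_index(defs.msp_pair)
    nsp_i = pair_index(defs.nsp_pair)
    ctp_i = pair_index(defs.control_pair)
    membrane_msp = sum(cell.p for cell in world.cells.values())
    row["msp"] = int(world.pep[:, :, msp_i].sum()) + membrane_msp \
        + bound_pairs[defs.msp_pair]
    row["nsp"] = int(world.pep[:, :, nsp_i].sum()) + bound_pairs[defs.nsp_pair]
    row["ctp"] = int(world.pep[:, :, ctp_i].sum()) \
        + bound_pairs[defs.control_pair]

    row["npre"] = int(world.npre.sum())
    row["apre"] = int(world.apre.sum())
    row["aapre"] = int(world.aapre.sum())
    row["nt"] = int(world.nt.sum())
    row["am_free"] = int(world.am.sum() + world.am_out.sum())
    row["am_membrane"] = sum(cell.b for cell in world.cells.values())
    row["aa"] = int(world.aa.sum())
    row["rna_strands"] = n_strands
    row["rna_residues"] = n_residues
    row["peptides_free"] = int(world.pep.sum())
    return row


def write_series(rows, destination) -> pd.DataFrame:
    """Append-one-row-per-report CSV with the stable documented header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df = df.reindex(columns=CENSUS_COLUMNS, fill_value=0)
    df.to_csv(destination, index=False)
    return df


def read_series(source) -> pd.DataFrame:
    return pd.read_csv(source)


_WINNER_COLUMN = {"nsr": "nsr", "nspg": "nspg", "mspg": "mspg",
                  "ctpg": "ctpg", "ctr": "ctr"}


def declare_winner(series: pd.DataFrame, classes: Tuple[str, str]) -> str:
    """Competition call on a finished time series.

    The winner is the species whose competitor's gene count is zero at the
    final step while its own is positive; anything else is "undecided"
    ("extinction" when both ended at zero).
    """
    a, b = (c.lower() for c in classes)
    final = series.iloc[-1]
    na, nb = int(final[_WINNER_COLUMN[a]]), int(final[_WINNER_COLUMN[b]])
    if na > 0 and nb == 0:
        return a
    if nb > 0 and na == 0:
        return b
    if na == 0 and nb == 0:
        return "extinction"
    return "undecided"


def plot_series(series: pd.DataFrame, path=None):  # pragma: no cover
    """Three-panel protocells / genes / peptides figure (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 9))
    for col in ("C_mspg", "C_ctpg", "C_nsr", "C_nspg", "C_mspg_nsr",
                "C_mspg_nspg", "C_empty"):
        if series[col].any():
            axes[0].plot(series["step"], series[col], label=col)
    for col in ("mspg", "ctpg", "nsr", "ctr", "nspg"):
        if series[col].any():
            axes[1].plot(series["step"], series[col], label=col)
    for col in ("msp", "ctp", "nsp"):
        if series[col].any():
            axes[2].plot(series["step"], series[col], label=col)
    for ax, title in zip(axes, ("protocells", "genes", "peptides")):
        ax.set_ylabel(title)
        ax.legend(fontsize=7)
    axes[-1].set_xlabel("Monte Carlo step")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
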