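"""Mono/dinucleotide composition scan: GC content and observed/expected
dinucleotide ratios.

CpG O/E — the observed CG dinucleotide frequency over the product of C and
G mononucleotide frequencies — is ~1 when bases are independently
arranged, and strongly depressed (< 0.4) in bunyavirus genomes, making the
(GC, CpG O/E) plane a cheap fingerprint for corroborating which virus a
dark-matter segment belongs to.  Dinucleotides are counted with overlap on
the given strand; windows containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CompositionResult", "composition_scan", "composition_table"]

_BASES = "ACGT"


@dataclass
class CompositionResult:
    seq_id: str
    mono: dict[str, float]
    dinuc_oe: dict[str, float]
    gc: float

    @property
    def cpg_oe(self) -> float:
        return self.dinuc_oe["CG"]


def composition_scan(
    sequence: str, seq_id: str = "", both_strands: bool = False
) -> CompositionResult:
    """Mono frequencies, 16 dinucleotide O/E ratios, and GC content.

    O/E[XY] = f(XY) / (f(X) * f(Y)) with f over overlapping windows; an
    undefined ratio (absent mononucleotide) is reported as NaN.  With
    ``both_strands=True`` the sequence and its reverse complement are
    pooled before counting.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 nt")
    if both_strands:
        from .seq_io import revcomp

        seq = seq + "N" + revcomp(seq)  # N junction keeps windows separate
    mono_counts = {b: seq.count(b) for b in _BASES}
    n_mono = sum(mono_counts.values())
    if n_mono == 0:
        raise ValueError("sequence contains no unambiguous bases")
    mono = {b: mono_counts[b] / n_mono for b in _BASES}
    di_counts = {a + b: 0 for a, b in product(_BASES, repeat=2)}
    n_di = 0
    for i in range(len(seq) - 1):
        w = seq[i : i + 2]
        if w[0] in _BASES and w[1] in _BASES:
            di_counts[w] += 1
            n_di += 1
    dinuc_oe = {}
    for xy, count in di_counts.items():
        expected = mono[xy[0]] * mono[xy[1]]
        if n_di == 0 or expected == 0:
            dinuc_oe[xy] = float("nan")
        else:
            dinuc_oe[xy] = (count / n_di) / expected
    return CompositionResult(
        seq_id=seq_id, mono=mono, dinuc_oe=dinuc_oe, gc=mono["G"] + mono["C"]
    )


def composition_table(
    sequences: dict[str, str],
    reference_panel: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(seq_id, gc, cpg_oe) table plus a nearest-neighbour concordance
    report in the (gc, cpg_oe) plane.

    Reference-panel sequences are included in the table (flagged) and are
    eligible neighbours; each query's row in the report names its nearest
    other sequence by Euclidean distance.
    """
    if not sequences:
        raise ValueError("no sequences")
    rows = []
    for sid, seq in sequences.items():
        res = composition_scan(seq, seq_id=sid)
        rows.append({"seq_id": sid, "gc": res.gc, "cpg_oe": res.cpg_oe, "panel": False})
    for sid, seq in (reference_panel or {}).items():
        res = composition_scan(seq, seq_id=sid)
        rows.append({"seq_id": sid, "gc": res.gc, "cpg_oe": res.cpg_oe, "panel": True})
    table = pd.DataFrame(rows).set_index("seq_id")
    coords = table[["gc", "cpg_oe"]].values
    report_rows = []
    for i, sid in enumerate(table.index):
        if table["panel"].iloc[i]:
            continue
        dists = np.linalg.norm(coords - coords[i], axis=1)
        dists[np.isnan(dists)] = np.inf  # sequences lacking C or G have no CpG O/E
        dists[i] = np.inf
        if np.isfinite(dists).any() and len(table) > 1:
            j = int(np.argmin(dists))
            report_rows.append(
                {
                    "seq_id": sid,
                    "nearest": table.index[j],
                    "distance": float(dists[j]),
                    "nearest_is_panel": bool(table["panel"].iloc[j]),
                }
            )
    report = pd.DataFrame(report_rows)
    return table, report
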