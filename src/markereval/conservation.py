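"""Per-column composition and alignment variability statistics.

A column is *variable* when at least two distinct concrete bases (A, C, G, T)
occur in it.  Gaps and ambiguity codes never create variability on their own:
a column reading A/A/-/N is invariant.  This is the conservative convention
of standard phylogenetics software, where ambiguity reflects uncertain base
calls rather than observed polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .alignment import AMBIGUITY_CODES, Alignment, BASES, GAP


@dataclass(frozen=True)
class ColumnProfile:
    """Character tallies for one alignment column (1-based)."""

    column: int
    counts: dict
    n_gap: int
    n_ambiguous: int
    distinct_bases: int


@dataclass(frozen=True)
class VariabilityReport:
    n_columns: int
    n_variable: int

    @property
    def fraction_variable(self) -> float:
        return self.n_variable / self.n_columns


def column_profile(aln: Alignment, column: int) -> ColumnProfile:
    """Exact tallies for one column.

    `counts` covers every character present; ambiguity codes are additionally
    summarized in `n_ambiguous` and do not enter `distinct_bases`.
    """
    chars = aln.column(column)
    counts: dict = {}
    for ch in chars:
        counts[ch] = counts.get(ch, 0) + 1
    n_gap = counts.get(GAP, 0)
    n_ambiguous = sum(v for k, v in counts.items() if k in AMBIGUITY_CODES)
    distinct = sum(1 for b in BASES if counts.get(b, 0) > 0)
    return ColumnProfile(column, counts, n_gap, n_ambiguous, distinct)


def variable_columns(aln: Alignment) -> np.ndarray:
    """Boolean mask over columns: True where >= 2 distinct bases occur."""
    codes = aln.to_codes()
    n_distinct = np.zeros(aln.length, dtype=np.int64)
    for b in range(4):
        n_distinct += (codes == b).any(axis=0)
    return n_distinct >= 2


def count_variable_sites(aln: Alignment) -> VariabilityReport:
    """Count variable columns over the full alignment length.

    The denominator is the full (trimmed) alignment length, including gap
    columns — reports always carry both the count and the length so the
    fraction is interpretable.
    """
    mask = variable_columns(aln)
    return VariabilityReport(n_columns=aln.length, n_variable=int(mask.sum()))


def conservation_table(aln: Alignment) -> pd.DataFrame:
    """Per-column profile table (one row per column) for TSV export."""
    mask = variable_columns(aln)
    rows = []
    for col in range(1, aln.length + 1):
        prof = column_profile(aln, col)
        rows.append(
            {
                "column": col,
                "A": prof.counts.get("A", 0),
                "C": prof.counts.get("C", 0),
                "G": prof.counts.get("G", 0),
                "T": prof.counts.get("T", 0),
                "gap": prof.n_gap,
                "ambiguous": prof.n_ambiguous,
                "distinct_bases": prof.distinct_bases,
                "variable": int(mask[col - 1]),
            }
        )
    return pd.DataFrame(rows)


def write_conservation_report(
    aln: Alignment, tsv_path: Union[str, "object"], report: VariabilityReport
) -> None:
    """Write the per-column TSV with a trailing summary row."""
    df = conservation_table(aln)
    with open(tsv_path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# n_columns={report.n_columns}\tn_variable={report.n_variable}\t"
            f"fraction_variable={report.fraction_variable:.3f}\n"
        )
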