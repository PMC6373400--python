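"""Pairwise percent identity and its intra-/inter-specific partition.

Identity between two aligned rows uses *pairwise deletion*: columns where
either sequence carries a gap or an ambiguity code are excluded, and percent
identity is 100 × matches / comparable over the rest.  An optional relaxed
rule ("overlap") instead counts an ambiguity-code pair as a match when the
two characters' IUPAC expansions intersect; the strict exclusion rule is the
default and is stamped into every report header.

The partition step splits off-diagonal identities into within-species and
between-species pools and computes the barcoding-gap statistic

    gap = min(intraspecific identities) − max(interspecific identities)

which is positive exactly when an identity threshold cleanly separates
conspecific from heterospecific pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .alignment import Alignment, IUPAC_EXPANSION, StrainTable


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used in printed identity tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pairwise_identity(
    a: str, b: str, ambiguity: str = "exclude"
) -> Tuple[Optional[float], int]:
    """Percent identity between two equal-length gapped sequences.

    Returns ``(percent, comparable)``; percent is None when no column is
    comparable (the pair is *undefined*).

    ambiguity
        "exclude" (default): drop columns where either character is a gap or
        an ambiguity code.  "overlap": drop only gap columns; two characters
        match when their IUPAC expansions intersect.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if ambiguity == "exclude":
        comparable = 0
        matches = 0
        for ca, cb in zip(a, b):
            if ca in "ACGT" and cb in "ACGT":
                comparable += 1
                if ca == cb:
                    matches += 1
    elif ambiguity == "overlap":
        comparable = 0
        matches = 0
        for ca, cb in zip(a, b):
            ea, eb = IUPAC_EXPANSION[ca], IUPAC_EXPANSION[cb]
            if ea and eb:
                comparable += 1
                if ea & eb:
                    matches += 1
    else:
        raise ValueError(f"unknown ambiguity rule {ambiguity!r}")
    if comparable == 0:
        return None, 0
    return 100.0 * matches / comparable, comparable


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with per-pair comparable-site counts.

    ``values`` holds NaN for undefined pairs (zero comparable columns);
    those pairs are listed in ``undefined_pairs``.
    """

    ids: list
    values: np.ndarray
    comparable_sites: np.ndarray
    ambiguity: str = "exclude"

    @property
    def undefined_pairs(self) -> list:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def identity_matrix(aln: Alignment, ambiguity: str = "exclude") -> IdentityMatrix:
    """All-pairs percent identity under pairwise deletion.

    Vectorized over the integer-encoded alignment; equivalent to calling
    :func:`pairwise_identity` on every unordered pair.
    """
    if aln.n_sequences < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    codes = aln.to_codes()
    n = aln.n_sequences
    values = np.full((n, n), np.nan)
    comp = np.zeros((n, n), dtype=np.int64)
    if ambiguity == "exclude":
        is_base = codes < 4
        for i in range(n):
            both = is_base[i] & is_base[i + 1:]
            eq = (codes[i] == codes[i + 1:]) & both
            c = both.sum(axis=1)
            m = eq.sum(axis=1)
            comp[i, i + 1:] = c
            with np.errstate(invalid="ignore", divide="ignore"):
                values[i, i + 1:] = np.where(c > 0, 100.0 * m / c, np.nan)
        # diagonal: self-comparison over a sequence's own non-gap, non-ambiguous sites
        for i in range(n):
            c = int(is_base[i].sum())
            comp[i, i] = c
            values[i, i] = 100.0 if c > 0 else np.nan
    elif ambiguity == "overlap":
        for i in range(n):
            for j in range(i, n):
                pct, c = pairwise_identity(
                    aln.records[i][1], aln.records[j][1], ambiguity="overlap"
                )
                values[i, j] = np.nan if pct is None else pct
                comp[i, j] = c
    else:
        raise ValueError(f"unknown ambiguity rule {ambiguity!r}")
    iu = np.triu_indices(n, 1)
    values[(iu[1], iu[0])] = values[iu]
    comp[(iu[1], iu[0])] = comp[iu]
    return IdentityMatrix(list(aln.ids), values, comp, ambiguity)


@dataclass
class SimilarityPartition:
    """Intra- vs inter-specific identity pools and the barcoding-gap statistic."""

    intra: dict            # species -> list of percent identities
    inter: dict            # (species_a, species_b) sorted tuple -> list
    n_unassigned_pairs: int
    n_undefined_pairs: int

    @property
    def intra_values(self) -> list:
        return [v for vals in self.intra.values() for v in vals]

    @property
    def inter_values(self) -> list:
        return [v for vals in self.inter.values() for v in vals]

    @property
    def intra_range(self) -> Optional[Tuple[float, float]]:
        vals = self.intra_values
        return (min(vals), max(vals)) if vals else None

    @property
    def inter_range(self) -> Optional[Tuple[float, float]]:
        vals = self.inter_values
        return (min(vals), max(vals)) if vals else None

    @property
    def gap(self) -> Optional[float]:
        """min(intra) − max(inter), in percentage points; negative when the
        intra and inter distributions overlap."""
        if not self.intra_values or not self.inter_values:
            return None
        return min(self.intra_values) - max(self.inter_values)

    @property
    def has_gap(self) -> bool:
        g = self.gap
        return g is not None and g > 0

    def summary(self, ndigits: int = 1) -> dict:
        """JSON-ready summary; printed values rounded half-up."""
        rng = lambda r: None if r is None else [
            round_half_up(r[0], ndigits), round_half_up(r[1], ndigits)
        ]
        return {
            "n_intra_pairs": len(self.intra_values),
            "n_inter_pairs": len(self.inter_values),
            "n_unassigned_pairs": self.n_unassigned_pairs,
            "n_undefined_pairs": self.n_undefined_pairs,
            "intra_range": rng(self.intra_range),
            "inter_range": rng(self.inter_range),
            "gap": None if self.gap is None else round_half_up(self.gap, ndigits),
            "has_gap": self.has_gap,
        }


def partition_similarities(
    m: IdentityMatrix, table: StrainTable
) -> SimilarityPartition:
    """Split off-diagonal identities into intra- and inter-specific pools.

    Pairs involving an unassigned strain are counted but excluded from both
    pools, as are undefined pairs.  Species represented by a single strain
    contribute only to the inter pool.
    """
    labeled = [sid for sid in m.ids if sid in table and table.is_labeled(sid)]
    if len(labeled) < 2:
        raise ValueError("need at least 2 labeled strains to partition")
    intra: dict = {}
    inter: dict = {}
    n_unassigned = 0
    n_undefined = 0
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = m.ids[i], m.ids[j]
            if not (a in table and table.is_labeled(a)
                    and b in table and table.is_labeled(b)):
                n_unassigned += 1
                continue
            v = m.values[i, j]
            if np.isnan(v):
                n_undefined += 1
                continue
            sa, sb = table.species_of(a), table.species_of(b)
            if sa == sb:
                intra.setdefault(sa, []).append(float(v))
            else:
                key = tuple(sorted((sa, sb)))
                inter.setdefault(key, []).append(float(v))
    return SimilarityPartition(intra, inter, n_unassigned, n_undefined)


def write_identity_matrix(m: IdentityMatrix, path: Union[str, "object"]) -> None:
    """Write the strains × strains matrix as TSV; header records the gap rule."""
    with open(path, "w") as fh:
        fh.write(f"# percent identity, pairwise deletion, ambiguity={m.ambiguity}\n")
        m.to_frame().to_csv(fh, sep="\t", float_format="%.6f")
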