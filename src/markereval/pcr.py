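"""In-silico PCR with IUPAC-degenerate primers.

Matching is positional: primer base and template base match when their
IUPAC expansions intersect (so primer Y matches template C or T but not A
or G, and either side may carry degeneracy).  The reverse primer is given
5'→3' on the reverse strand, as in wet-lab convention, and is therefore
matched as its reverse complement on the supplied strand.  A product spans
the first base of a forward hit through the last base of a downstream
reverse-complement hit, 1-based inclusive; all products are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .alignment import IUPAC_EXPANSION

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    seq = seq.upper()
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'→3' on their own strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            p = primer.upper()
            if not p:
                raise ValueError(f"{name} primer is empty")
            for ch in p:
                if ch not in IUPAC_EXPANSION or ch == "-":
                    raise ValueError(
                        f"{name} primer contains non-IUPAC character {ch!r}"
                    )
        object.__setattr__(self, "forward", self.forward.upper().replace("U", "T"))
        object.__setattr__(self, "reverse", self.reverse.upper().replace("U", "T"))


def _bases_match(primer_ch: str, template_ch: str) -> bool:
    return bool(IUPAC_EXPANSION[primer_ch] & IUPAC_EXPANSION[template_ch])


def _find_sites(pattern: str, template: str, max_mismatches: int) -> List[int]:
    """0-based start positions where `pattern` matches with at most
    `max_mismatches` positional mismatches."""
    hits = []
    m, n = len(pattern), len(template)
    for start in range(n - m + 1):
        mism = 0
        for k in range(m):
            if not _bases_match(pattern[k], template[start + k]):
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            hits.append(start)
    return hits


@dataclass(frozen=True)
class PcrProduct:
    start: int            # 1-based, first base of the forward site
    end: int              # 1-based, last base of the reverse-complement site
    length: int


def in_silico_pcr(
    template: str, primers: PrimerPair, max_mismatches: int = 0
) -> List[PcrProduct]:
    """Predict amplicons of a primer pair on an ungapped template.

    Returns every (forward site, non-overlapping downstream reverse site)
    combination, sorted by start then end; empty list when nothing amplifies.
    """
    template = template.upper().replace("U", "T")
    for i, ch in enumerate(template, start=1):
        if ch not in IUPAC_EXPANSION or ch == "-":
            raise ValueError(f"non-IUPAC template character {ch!r} at position {i}")
    fwd_sites = _find_sites(primers.forward, template, max_mismatches)
    rev_pattern = reverse_complement(primers.reverse)
    rev_sites = _find_sites(rev_pattern, template, max_mismatches)
    products = []
    for f in fwd_sites:
        f_end = f + len(primers.forward)          # exclusive
        for r in rev_sites:
            if r < f_end:                         # sites must not overlap
                continue
            end = r + len(rev_pattern)            # exclusive
            products.append(PcrProduct(f + 1, end, end - f))
    products.sort(key=lambda p: (p.start, p.end))
    return products
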