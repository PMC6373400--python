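"""Species-diagnostic SNP discovery, codon annotation and query classification.

A *diagnostic site* for a target species is an alignment column where every
target strain carries one and the same concrete base while no other labeled
strain carries it.  The scan is asymmetric about ambiguity on purpose: a
diagnostic claim needs positive evidence, so target strains must be
unambiguous (a gapped or ambiguous target cell disqualifies the column),
whereas a background ambiguity code counts *against* the site whenever its
IUPAC expansion includes the candidate base — an N in the background could
be the diagnostic base, so the column is rejected in strict mode.

Relaxed mode tolerates up to ``max_exceptions`` background carriers and
reports their number; strict mode is relaxed(0).

Annotation maps a site to full-gene coordinates, reads the reference codon,
substitutes each observed background base at the site's codon position and
decides synonymy under the standard genetic code — against the states
actually observed, not all three alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import pandas as pd

from .alignment import (
    Alignment,
    BASES,
    CoordinateMap,
    GAP,
    IUPAC_EXPANSION,
    StrainTable,
    codon_context,
    column_to_gene_position,
    gene_position_of_codon,
    translate_codon,
)


@dataclass(frozen=True)
class CodonAnnotation:
    codon_index: int
    codon_position: int          # 1 | 2 | 3
    ref_codon: str
    alt_codons: frozenset
    ref_aa: str
    alt_aas: frozenset

    @property
    def is_synonymous(self) -> bool:
        """True iff every observed alternative codon encodes the reference
        amino acid."""
        return self.alt_aas == frozenset({self.ref_aa})


@dataclass(frozen=True)
class DiagnosticSite:
    species: str
    column: int                  # 1-based alignment column
    state: str                   # concrete base shared by all target strains
    background_states: frozenset
    n_target: int
    n_background_with_state: int
    gene_position: Optional[int] = None
    codon: Optional[CodonAnnotation] = None


def find_diagnostic_snps(
    aln: Alignment,
    table: StrainTable,
    target: str,
    mode: str = "strict",
    max_exceptions: int = 0,
) -> list:
    """Scan every column for bases unique to the target species.

    mode
        "strict": no background strain may carry the candidate base (an
        ambiguity code carries it when its expansion includes it).
        "relaxed": up to `max_exceptions` background carriers allowed;
        their count is reported per site.

    Background = every labeled strain not in the target species; unassigned
    strains are ignored entirely.  Output is sorted by column.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "strict":
        max_exceptions = 0
    labeled = [sid for sid in aln.ids if sid in table and table.is_labeled(sid)]
    target_ids = [sid for sid in labeled if table.species_of(sid) == target]
    background_ids = [sid for sid in labeled if table.species_of(sid) != target]
    if not target_ids:
        raise ValueError(f"species {target!r} has no labeled strains in the alignment")
    if not background_ids:
        raise ValueError(f"no labeled background strains outside {target!r}")

    tgt_rows = [aln.sequence(sid) for sid in target_ids]
    bkg_rows = [aln.sequence(sid) for sid in background_ids]
    sites = []
    for col in range(1, aln.length + 1):
        tgt_chars = {row[col - 1] for row in tgt_rows}
        if len(tgt_chars) != 1:
            continue
        (state,) = tgt_chars
        if state not in BASES:      # gapped or ambiguous target cell
            continue
        bkg_chars = [row[col - 1] for row in bkg_rows]
        carriers = sum(1 for ch in bkg_chars if state in IUPAC_EXPANSION[ch])
        if carriers > max_exceptions:
            continue
        background = frozenset(ch for ch in bkg_chars if ch != GAP)
        sites.append(
            DiagnosticSite(
                species=target,
                column=col,
                state=state,
                background_states=background,
                n_target=len(target_ids),
                n_background_with_state=carriers,
            )
        )
    return sites


def _reference_codon(
    codon_index: int,
    cmap: CoordinateMap,
    ref_fragment: str,
    reference_gene: Optional[str],
) -> str:
    start = gene_position_of_codon(codon_index, 1, cmap.frame_start)
    if reference_gene is not None:
        gene = reference_gene.upper().replace("U", "T")
        frag_in_gene = gene[cmap.gene_offset:cmap.gene_offset + len(ref_fragment)]
        if frag_in_gene != ref_fragment:
            raise ValueError(
                "reference gene does not contain the aligned fragment at "
                f"gene_offset={cmap.gene_offset}"
            )
        if start + 2 > len(gene):
            raise ValueError(
                f"codon {codon_index} extends past the reference gene end"
            )
        return gene[start - 1:start + 2]
    # fall back to the ungapped fragment when the codon lies wholly inside it
    frag_start = start - cmap.gene_offset
    if frag_start < 1 or frag_start + 2 > len(ref_fragment):
        raise ValueError(
            f"codon incomplete: codon {codon_index} overlaps the fragment "
            "boundary and no full gene sequence was supplied"
        )
    return ref_fragment[frag_start - 1:frag_start + 2]


def annotate_site(
    site: DiagnosticSite,
    aln: Alignment,
    cmap: CoordinateMap,
    reference_gene: Optional[str] = None,
) -> DiagnosticSite:
    """Enrich a site with gene position and codon context.

    Pure enrichment: species, column and state are never altered.  Observed
    background ambiguity codes are expanded to concrete bases for the
    alternative-codon set; the diagnostic state itself and gaps are dropped
    from the alternatives.
    """
    gene_pos = column_to_gene_position(aln, cmap, site.column)
    codon_index, codon_pos = codon_context(gene_pos, cmap.frame_start)
    ref = aln.sequence(cmap.reference_strain).replace(GAP, "")
    ref_codon = _reference_codon(codon_index, cmap, ref, reference_gene)
    if ref_codon[codon_pos - 1] != site.state:
        # the reference strain need not be in the target species; annotate
        # relative to the codon actually observed in the reference
        pass
    alt_bases = set()
    for ch in site.background_states:
        alt_bases |= IUPAC_EXPANSION[ch]
    alt_bases.discard(site.state)
    alt_codons = frozenset(
        ref_codon[:codon_pos - 1] + b + ref_codon[codon_pos:] for b in sorted(alt_bases)
    )
    ref_aa = translate_codon(ref_codon)
    alt_aas = frozenset(translate_codon(c) for c in alt_codons)
    ann = CodonAnnotation(
        codon_index=codon_index,
        codon_position=codon_pos,
        ref_codon=ref_codon,
        alt_codons=alt_codons,
        ref_aa=ref_aa,
        alt_aas=alt_aas,
    )
    return replace(site, gene_position=gene_pos, codon=ann)


#: classification outcomes for classify_query
PRESENT, ABSENT, INCONCLUSIVE = "present", "absent", "inconclusive"


@dataclass(frozen=True)
class SiteEvidence:
    column: int
    expected_state: str
    observed: str
    match: Optional[bool]        # None for gap/ambiguous observation


def classify_query(query: str, panel: Sequence[DiagnosticSite]) -> dict:
    """Call species membership of an aligned query against a diagnostic panel.

    For each species in the panel: *present* when the query matches the
    diagnostic state at every site, *absent* when it carries a different
    concrete base at every site, *inconclusive* otherwise (gaps, ambiguity
    codes, or mixed evidence).  Returns species → (call, [SiteEvidence]).
    """
    if not panel:
        raise ValueError("empty diagnostic panel")
    query = query.upper().replace("U", "T")
    by_species: dict = {}
    for site in panel:
        by_species.setdefault(site.species, []).append(site)
    results = {}
    for species, sites in by_species.items():
        evidence = []
        for site in sites:
            if site.column > len(query):
                raise ValueError(
                    f"query length {len(query)} shorter than panel column {site.column}"
                )
            obs = query[site.column - 1]
            if obs == site.state:
                match: Optional[bool] = True
            elif obs in BASES:
                match = False
            else:
                match = None
            evidence.append(SiteEvidence(site.column, site.state, obs, match))
        flags = [e.match for e in evidence]
        if all(f is True for f in flags):
            call = PRESENT
        elif all(f is False for f in flags):
            call = ABSENT
        else:
            call = INCONCLUSIVE
        results[species] = (call, evidence)
    return results


def panel_to_frame(panel: Sequence[DiagnosticSite]) -> pd.DataFrame:
    rows = []
    for s in panel:
        rows.append(
            {
                "species": s.species,
                "column": s.column,
                "state": s.state,
                "background_states": "".join(sorted(s.background_states)),
                "n_target": s.n_target,
                "n_background_with_state": s.n_background_with_state,
                "gene_position": "" if s.gene_position is None else s.gene_position,
                "codon_index": "" if s.codon is None else s.codon.codon_index,
                "codon_position": "" if s.codon is None else s.codon.codon_position,
                "ref_codon": "" if s.codon is None else s.codon.ref_codon,
                "is_synonymous": "" if s.codon is None else str(s.codon.is_synonymous).lower(),
            }
        )
    return pd.DataFrame(rows)


def write_panel(panel: Sequence[DiagnosticSite], path: Union[str, "object"]) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_panel(path: Union[str, "object"]) -> list:
    """Read a panel TSV back into DiagnosticSite objects (annotation columns
    other than gene position are not reconstructed)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    panel = []
    for _, row in df.iterrows():
        panel.append(
            DiagnosticSite(
                species=row["species"],
                column=int(row["column"]),
                state=row["state"],
                background_states=frozenset(row.get("background_states", "")),
                n_target=int(row["n_target"]) if row.get("n_target") else 0,
                n_background_with_state=(
                    int(row["n_background_with_state"])
                    if row.get("n_background_with_state") else 0
                ),
                gene_position=(
                    int(row["gene_position"]) if row.get("gene_position") else None
                ),
            )
        )
    return panel
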