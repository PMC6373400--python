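"""Synthetic labeled alignments with full ground truth.

The generator emulates a single-gene survey of a bacterial genus: a root
sequence, one ancestor per species radiating from it (star phylogeny), and
strains sampled around each ancestor.  Substitutions follow a
Jukes-Cantor-style per-site process with an optional transition bias: a
branch of length t substitutes each site with probability
3/4·(1 − e^(−4t/3)), which is exactly the JC transition probability, so
branch lengths compose additively and realized pairwise divergences match
their expectations without simulating continuous time.

``intra_divergence`` and ``inter_divergence`` are *pairwise* expectations:
the expected substitutions/site between two strains of the same species and
between two strains of different species.  Internally the root→ancestor
branch is (inter − intra)/2 and the ancestor→strain branch is intra/2, so
both pair classes hit their targets.

Planted diagnostic sites are applied after strain generation and are
excluded from every random process (mutation and gap injection), so
diagnostic-scan recovery of a planted site is guaranteed by construction,
not merely probable.  Outliers are strains *relabeled* (not resequenced) to
a different species, emulating misnamed database entries; species named in
planted sites are never involved, which preserves the planted-site
guarantee.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .alignment import Alignment, StrainEntry, StrainTable

_BASES = "ACGT"

# default strain allocation mirrors a realistic survey: one densely sampled
# focal species (22 strains), 20 species with 2 strains, 7 singletons
# = 69 strains in 28 species.
_DEFAULT_STRAINS = (22,) + (2,) * 20 + (1,) * 7


def jc_expected_p(d: float) -> float:
    """Expected differing-site proportion at pairwise divergence d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_divergence_for_identity(identity_percent: float) -> float:
    """Invert the JC expectation: identity (%) → substitutions/site."""
    p = 1.0 - identity_percent / 100.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise ValueError(f"identity {identity_percent}% is below the JC floor (25%)")
    return -0.75 * math.log(arg)


@dataclass
class SimulationParams:
    """Study-scale defaults: 69 strains, 28 species, 733 columns, one planted
    diagnostic site for the focal species, divergences calibrated so that
    within-species identity averages ≈ 98.6% and between-species ≈ 88.7%."""

    n_species: int = 28
    strains_per_species: Union[int, Sequence[int]] = _DEFAULT_STRAINS
    n_columns: int = 733
    inter_divergence: float = jc_divergence_for_identity(88.7)   # ≈ 0.1224
    intra_divergence: float = jc_divergence_for_identity(98.55)  # ≈ 0.0146
    planted_sites: Sequence[Tuple[str, int, str]] = (("species_01", 225, "G"),)
    n_outliers: int = 0
    gap_fraction: float = 0.005
    kappa: float = 2.0
    seed: int = 0

    def species_labels(self) -> List[str]:
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]

    def strain_counts(self) -> List[int]:
        if isinstance(self.strains_per_species, int):
            return [self.strains_per_species] * self.n_species
        counts = list(self.strains_per_species)
        if len(counts) != self.n_species:
            raise ValueError(
                f"strains_per_species has {len(counts)} entries for "
                f"{self.n_species} species"
            )
        return counts

    def validate(self) -> None:
        if self.n_species < 1 or self.n_columns < 1:
            raise ValueError("n_species and n_columns must be >= 1")
        for name, d in (("intra", self.intra_divergence), ("inter", self.inter_divergence)):
            if not 0.0 <= d < 0.75:
                raise ValueError(f"{name}_divergence {d} outside [0, 0.75)")
        if self.inter_divergence < self.intra_divergence:
            raise ValueError("inter_divergence must be >= intra_divergence")
        if not 0.0 <= self.gap_fraction < 0.5:
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if any(c < 1 for c in self.strain_counts()):
            raise ValueError("every species needs >= 1 strain")
        labels = set(self.species_labels())
        seen_cols: dict = {}
        for sp, col, state in self.planted_sites:
            if sp not in labels:
                raise ValueError(f"planted site references unknown species {sp!r}")
            if not 1 <= col <= self.n_columns:
                raise ValueError(f"planted column {col} outside 1..{self.n_columns}")
            if state not in _BASES:
                raise ValueError(f"planted state {state!r} is not a concrete base")
            if col in seen_cols and seen_cols[col] != sp:
                raise ValueError(
                    f"planted state conflict: column {col} claimed by "
                    f"{seen_cols[col]!r} and {sp!r}"
                )
            seen_cols[col] = sp


@dataclass
class SyntheticTruth:
    """Everything the generator knows about its own output."""

    species_ancestors: dict                # species -> ungapped sequence
    generating_species: dict               # strain -> species it was drawn from
    planted_sites: list                    # (species, column, state)
    variable_columns: list                 # 1-based, realized in the alignment
    outliers: list                         # strains whose label != generating species
    params_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_ancestors": self.species_ancestors,
                "generating_species": self.generating_species,
                "planted_sites": [list(t) for t in self.planted_sites],
                "variable_columns": self.variable_columns,
                "outliers": self.outliers,
                "seed": self.params_seed,
            },
            indent=2,
            sort_keys=True,
        )


def _branch_sub_prob(t: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _mutate(
    seq: np.ndarray,
    p_sub: float,
    mutable: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One JC-style branch: substitute each mutable site with prob p_sub;
    the replacement is the transition partner with weight kappa against
    weight 1 for each transversion."""
    out = seq.copy()
    hit = (rng.random(seq.size) < p_sub) & mutable
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return out
    u = rng.random(idx.size)
    w = kappa + 2.0
    old = seq[idx]
    new = np.empty(idx.size, dtype=seq.dtype)
    transition = u < kappa / w
    first_tv = (~transition) & (u < (kappa + 1.0) / w)
    # transition partner: A<->G (0<->2), C<->T (1<->3)
    new[transition] = (old[transition] + 2) % 4
    # transversions: the two bases of the opposite purine/pyrimidine class
    new[first_tv] = (old[first_tv] + 1) % 4
    rest = ~transition & ~first_tv
    new[rest] = (old[rest] + 3) % 4
    out[idx] = new
    return out


def generate_dataset(
    params: SimulationParams,
) -> Tuple[Alignment, StrainTable, SyntheticTruth]:
    """Simulate an alignment + strain table with complete ground truth.

    RNG consumption order is fixed (root → ancestors → strains → planted
    resampling → gaps → outliers), so output is bit-reproducible from the
    seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.n_columns
    species = params.species_labels()
    counts = params.strain_counts()

    planted_cols = np.array([c - 1 for _, c, _ in params.planted_sites], dtype=int)
    mutable = np.ones(L, dtype=bool)
    if planted_cols.size:
        mutable[planted_cols] = False

    t_anc = max(params.inter_divergence - params.intra_divergence, 0.0) / 2.0
    t_strain = params.intra_divergence / 2.0
    p_anc = _branch_sub_prob(t_anc)
    p_strain = _branch_sub_prob(t_strain)

    root = rng.integers(0, 4, size=L).astype(np.int8)
    ancestors = {
        sp: _mutate(root, p_anc, mutable, params.kappa, rng) for sp in species
    }

    strain_ids: List[str] = []
    generating: dict = {}
    rows: List[np.ndarray] = []
    for sp, count in zip(species, counts):
        for k in range(count):
            sid = f"{sp}_strain{k + 1:02d}"
            strain_ids.append(sid)
            generating[sid] = sp
            rows.append(_mutate(ancestors[sp], p_strain, mutable, params.kappa, rng))
    mat = np.vstack(rows)

    # planted diagnostic states: target strains fixed; every other species
    # gets one resampled base != state, shared by its strains so that
    # planting never creates within-species variation
    for sp, col, state in params.planted_sites:
        c = col - 1
        s = _BASES.index(state)
        alt = [b for b in range(4) if b != s]
        bkg_state = {
            other: alt[int(rng.integers(0, 3))] for other in species if other != sp
        }
        for i, sid in enumerate(strain_ids):
            gen = generating[sid]
            mat[i, c] = s if gen == sp else bkg_state[gen]

    # uniform gap injection outside planted columns
    gap_mask = rng.random(mat.shape) < params.gap_fraction
    if planted_cols.size:
        gap_mask[:, planted_cols] = False

    # outliers: relabel strains, avoiding species involved in planted sites
    planted_species = {sp for sp, _, _ in params.planted_sites}
    eligible = [
        sid for sid in strain_ids if generating[sid] not in planted_species
    ]
    eligible_species = [sp for sp in species if sp not in planted_species]
    if params.n_outliers > len(eligible):
        raise ValueError(
            f"cannot plant {params.n_outliers} outliers: only {len(eligible)} "
            "strains outside planted species"
        )
    if params.n_outliers > 0 and len(eligible_species) < 2:
        raise ValueError("outlier planting needs >= 2 species without planted sites")
    outlier_ids = [
        eligible[i]
        for i in rng.choice(len(eligible), size=params.n_outliers, replace=False)
    ]
    labels = dict(generating)
    for sid in outlier_ids:
        choices = [sp for sp in eligible_species if sp != generating[sid]]
        labels[sid] = choices[int(rng.integers(0, len(choices)))]

    records = []
    first_of_species: dict = {}
    entries: dict = {}
    for i, sid in enumerate(strain_ids):
        chars = np.array(list(_BASES))[mat[i]]
        chars[gap_mask[i]] = "-"
        records.append((sid, "".join(chars)))
        sp = labels[sid]
        is_type = first_of_species.setdefault(generating[sid], sid) == sid and sid not in outlier_ids
        entries[sid] = StrainEntry(sp, accession=None, is_type_strain=is_type)
    aln = Alignment(records)
    table = StrainTable(entries)

    from .conservation import variable_columns as _varcols

    truth = SyntheticTruth(
        species_ancestors={
            sp: "".join(np.array(list(_BASES))[anc]) for sp, anc in ancestors.items()
        },
        generating_species=generating,
        planted_sites=[tuple(t) for t in params.planted_sites],
        variable_columns=[int(c) + 1 for c in np.flatnonzero(_varcols(aln))],
        outliers=sorted(outlier_ids),
        params_seed=params.seed,
    )
    return aln, table, truth


def calibrate_to_identity(
    target_intra_range: Tuple[float, float],
    target_inter_range: Tuple[float, float],
    seed: int = 0,
    **overrides,
) -> SimulationParams:
    """Divergence parameters whose expected identities sit at the interval
    midpoints, via the Jukes-Cantor back-mutation adjustment
    p = 3/4·(1 − e^(−4d/3))."""
    for name, (lo, hi) in (
        ("intra", target_intra_range),
        ("inter", target_inter_range),
    ):
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError(f"infeasible {name} identity interval ({lo}, {hi})")
    intra_mid = sum(target_intra_range) / 2.0
    inter_mid = sum(target_inter_range) / 2.0
    if intra_mid <= inter_mid:
        raise ValueError(
            "intraspecific identity target must lie above the interspecific target"
        )
    intra_d = jc_divergence_for_identity(intra_mid)
    inter_d = jc_divergence_for_identity(inter_mid)
    return SimulationParams(
        intra_divergence=intra_d,
        inter_divergence=inter_d,
        seed=seed,
        **overrides,
    )
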