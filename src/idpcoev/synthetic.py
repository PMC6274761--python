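"""Synthetic paired MSAs with planted interprotein couplings, and matching
synthetic complex structures.

The generator emulates the two inputs of the real analysis without any
database access:

* a paired alignment over ``n_species`` rows in which selected
  (IDP column, partner column) pairs co-vary with tunable strength, on a
  star-tree phylogeny with tunable redundancy (near-duplicate descendants of
  shared ancestors), and
* a complex of a short IDP chain (ideal helix or extended strand) bound to a
  compact three-helix-bundle decoy partner, in which every planted pair is
  placed within atomic-contact range.

The coupled-pair sampler draws the IDP column state from its background
frequencies and, with probability equal to the coupling strength, copies it
through a fixed random permutation into the partner column; otherwise the
partner state is drawn independently. This yields a mutual information that
increases monotonically with strength and is analytically transparent
(strength 1 with no mutation gives MI equal to the column entropy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from . import geometry
from .alignment import PairedAlignment
from .alphabet import AMINO_ACIDS
from .structure import ComplexStructure, NumberingMap, ResidueKey

N_AA = 20


class PlacementError(RuntimeError):
    """The requested planted-contact geometry cannot be realised."""


@dataclass(frozen=True)
class GeometryConfig:
    idp_conformation: str = "helix"  # "helix" | "extended"
    contact_distance_max: float = 5.0  # Angstrom
    unresolved_idp: tuple[int, ...] = ()  # 1-based IDP positions without coordinates
    idp_construct: tuple[int, int] | None = None  # 1-based inclusive construct range


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic complex.

    ``planted_pairs`` entries are (idp_col, partner_col, strength) with
    1-based columns and strength in [0, 1]. ``redundancy`` r groups the
    ``n_species`` rows into ceil(n/r) star-tree ancestors with r mutated
    descendants each, so the row count stays fixed while the effective
    sample size shrinks. ``background_entropy`` is the target per-column
    Shannon entropy in bits (uniform over 20 states is ~4.32).
    """

    n_species: int = 500
    len_idp: int = 30
    len_partner: int = 40
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    background_entropy: float = 3.0
    redundancy: int = 1
    mutation_rate: float = 0.05
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.len_idp < 1 or self.len_partner < 1:
            raise ValueError("protein lengths must be >= 1")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        seen_i, seen_j = set(), set()
        for i, j, s in self.planted_pairs:
            if not (1 <= i <= self.len_idp):
                raise ValueError(f"planted IDP column {i} outside 1..{self.len_idp}")
            if not (1 <= j <= self.len_partner):
                raise ValueError(f"planted partner column {j} outside 1..{self.len_partner}")
            if i in seen_i or j in seen_j:
                raise ValueError(f"planted column reused: ({i}, {j})")
            seen_i.add(i)
            seen_j.add(j)
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"coupling strength {s} outside [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth planted pairs (1-based columns); consumed only by tests
    and benchmarking code, never by the pipeline."""

    pairs: tuple[tuple[int, int], ...]
    strengths: tuple[float, ...]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("idp_col\tpartner_col\tstrength\n")
            for (i, j), s in zip(self.pairs, self.strengths):
                fh.write(f"{i}\t{j}\t{s}\n")


# ---------------------------------------------------------------------------
# alignment generation
# ---------------------------------------------------------------------------


def _background_frequencies(rng: np.random.Generator, n_cols: int,
                            target_bits: float) -> np.ndarray:
    """Per-column 20-state frequencies tempered to the target entropy."""
    target_bits = float(np.clip(target_bits, 0.05, math.log2(N_AA) - 1e-3))
    freqs = np.empty((n_cols, N_AA))
    for c in range(n_cols):
        base = rng.dirichlet(np.ones(N_AA))
        base = np.maximum(base, 1e-12)
        lo, hi = 0.0, 60.0  # temper exponent: 0 -> uniform, large -> peaked
        for _ in range(60):
            beta = 0.5 * (lo + hi)
            p = base ** beta
            p /= p.sum()
            h = -(p * np.log2(p)).sum()
            if h > target_bits:
                lo = beta
            else:
                hi = beta
        freqs[c] = p
    return freqs


def _sample_columns(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """Sample n rows, each column independent with its own frequencies."""
    u = rng.random((n, freqs.shape[0]))
    cum = np.cumsum(freqs, axis=1)
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)


def generate_paired_msa(config: SynthConfig) -> tuple[PairedAlignment, PlantedTruth]:
    """Generate a paired alignment with planted interprotein couplings.

    Deterministic for a fixed config (including seed). Columns are gap-free;
    rows are labelled sp0001..spNNNN in ancestor-major order.
    """
    rng = np.random.default_rng(config.seed)
    L = config.len_idp + config.len_partner
    freqs = _background_frequencies(rng, L, config.background_entropy)

    # fixed random one-to-one state maps, one per planted pair
    perms = [rng.permutation(N_AA) for _ in config.planted_pairs]

    n_anc = math.ceil(config.n_species / config.redundancy)
    ancestors = _sample_columns(rng, freqs, n_anc)
    for (i, j, strength), perm in zip(config.planted_pairs, perms):
        ci, cj = i - 1, config.len_idp + (j - 1)
        copy = rng.random(n_anc) < strength
        ancestors[copy, cj] = perm[ancestors[copy, ci]].astype(np.int8)

    rows = np.repeat(ancestors, config.redundancy, axis=0)[: config.n_species]
    if config.mutation_rate > 0:
        mutate = rng.random(rows.shape) < config.mutation_rate
        fresh = _sample_columns(rng, freqs, rows.shape[0])
        rows = np.where(mutate, fresh, rows)

    species = [f"sp{k + 1:04d}" for k in range(config.n_species)]
    aln = PairedAlignment(species, rows, boundary=config.len_idp)
    truth = PlantedTruth(
        pairs=tuple((i, j) for i, j, _ in config.planted_pairs),
        strengths=tuple(s for _, _, s in config.planted_pairs),
    )
    return aln, truth


# ---------------------------------------------------------------------------
# complex generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[k] for k in rng.integers(0, N_AA, size=n))


def _build_partner_bundle(n_res: int) -> dict[str, np.ndarray]:
    """Compact antiparallel three-helix-bundle decoy on ideal geometry.

    Short chains (< 18 residues) fall back to a single helix. Loop residues
    are placed on interpolated frames between helix ends; the decoy is not a
    physically continuous backbone through the loops, which is irrelevant for
    the surface/contact/secondary-structure uses it serves.
    """
    if n_res < 18:
        seg = geometry.build_backbone(n_res, *geometry.HELIX_PHI_PSI)
        return geometry.place_segment(seg, np.zeros(3), np.array([0.0, 0.0, 1.0]))

    loop_len = 3
    h = (n_res - 2 * loop_len) // 3
    lens = [h, h, n_res - 2 * loop_len - 2 * h]
    anchors = [np.array([0.0, 0.0, 0.0]),
               np.array([10.5, 0.0, 0.0]),
               np.array([5.25, 9.1, 0.0])]
    rise = 1.5
    directions = [np.array([0.0, 0.0, 1.0]),
                  np.array([0.0, 0.0, -1.0]),
                  np.array([0.0, 0.0, 1.0])]
    atoms: dict[str, list[np.ndarray]] = {k: [] for k in ("N", "CA", "C", "O", "CB")}
    seg_ends: list[np.ndarray] = []
    seg_starts: list[np.ndarray] = []
    for k, (ln, anchor, dirn) in enumerate(zip(lens, anchors, directions)):
        seg = geometry.build_backbone(ln, *geometry.HELIX_PHI_PSI)
        origin = anchor if dirn[2] > 0 else anchor + np.array([0, 0, (ln - 1) * rise])
        placed = geometry.place_segment(seg, origin, dirn, phase=0.7 * k)
        seg_starts.append(placed["CA"][0])
        seg_ends.append(placed["CA"][-1])
        if k > 0:  # loop connecting previous segment end to this start
            a, b = seg_ends[k - 1], seg_starts[k]
            # arc outward (in y and away from the bundle mid-plane in z)
            # so loop atoms clear the helix termini
            zc = 0.5 * (lens[0] - 1) * rise
            zdir = 1.0 if 0.5 * (a[2] + b[2]) >= zc else -1.0
            for t in np.linspace(0.25, 0.75, loop_len):
                bulge = float(np.sin(np.pi * t))
                ca = a + t * (b - a) + bulge * np.array([0.0, 3.0, 3.0 * zdir])
                for name, off in (("N", [-0.7, 0.9, 0.0]), ("CA", [0.0, 0.0, 0.0]),
                                  ("C", [0.7, -0.9, 0.3]), ("O", [1.6, -1.4, 0.3]),
                                  ("CB", [0.0, 1.2, -0.9])):
                    atoms[name].append(ca + np.asarray(off))
        for name in atoms:
            atoms[name].extend(placed[name])
    # reorder: we appended loop-then-segment for k>0, which is chain order
    return {name: np.stack(v) for name, v in atoms.items()}


def _min_dist(xa: np.ndarray, xb: np.ndarray) -> float:
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


def _rigid(params: np.ndarray, xyz: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(params[:3])
    if theta < 1e-12:
        R = np.eye(3)
    else:
        R = geometry.rodrigues(params[:3] / theta, theta)
    return (xyz - pivot) @ R.T + pivot + params[3:]


def generate_complex(config: SynthConfig, truth: PlantedTruth) -> ComplexStructure:
    """Build a synthetic complex realising the planted contacts.

    The partner decoy is built first; the IDP chain (ideal helix or extended
    strand) is then rigidly docked by minimising hinge penalties that pull
    every planted pair within ``contact_distance_max`` while keeping all
    interchain atom pairs above clash range. Raises :class:`PlacementError`
    when the constraints cannot be met.
    """
    geo = config.geometry
    if geo.contact_distance_max < 3.0:
        raise PlacementError(
            f"contact_distance_max {geo.contact_distance_max} Å is below "
            "heavy-atom contact range (>= 3 Å required)"
        )
    if geo.idp_conformation not in ("helix", "extended"):
        raise ValueError(f"unknown idp_conformation {geo.idp_conformation!r}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    phi_psi = (geometry.HELIX_PHI_PSI if geo.idp_conformation == "helix"
               else geometry.EXTENDED_PHI_PSI)
    idp = geometry.build_backbone(config.len_idp, *phi_psi)
    partner = _build_partner_bundle(config.len_partner)

    idp_seq = _random_sequence(rng, config.len_idp)
    partner_seq = _random_sequence(rng, config.len_partner)

    atom_order = ("N", "CA", "C", "O", "CB")
    n_idp_res = config.len_idp

    def flatten(atoms: dict[str, np.ndarray], seq: str):
        """Concatenate atom arrays, dropping glycine CB stubs."""
        n = len(seq)
        xyz = np.concatenate([atoms[t] for t in atom_order])
        res_of = np.tile(np.arange(n), len(atom_order))
        names = np.array([t for t in atom_order for _ in range(n)])
        keep = ~((names == "CB") & np.array([seq[r] == "G" for r in res_of]))
        return xyz[keep], res_of[keep], names[keep]

    idp_xyz, idp_res_of_atom, idp_atom_name = flatten(idp, idp_seq)
    partner_xyz, partner_res_of_atom, partner_atom_name = flatten(partner, partner_seq)

    pairs = [(i - 1, j - 1) for i, j in truth.pairs]
    target = max(3.2, geo.contact_distance_max - 0.8)
    clash_floor = 3.0

    idp_atoms_of = [np.where(idp_res_of_atom == r)[0] for r in range(n_idp_res)]
    partner_atoms_of = [np.where(partner_res_of_atom == r)[0]
                        for r in range(config.len_partner)]
    partner_tree = cKDTree(partner_xyz)

    def cost(params: np.ndarray) -> float:
        moved = _rigid(params, idp_xyz, idp_xyz.mean(axis=0))
        c = 0.0
        for (pi, qj) in pairs:
            d = _min_dist(moved[idp_atoms_of[pi]], partner_xyz[partner_atoms_of[qj]])
            c += 10.0 * max(0.0, d - target) ** 2
        near = partner_tree.query(moved, k=1)[0]
        close = near[near < clash_floor]
        c += 4.0 * float(((clash_floor - close) ** 2).sum())
        return c

    def acceptable(candidate: np.ndarray) -> tuple[bool, str]:
        for (pi, qj), (i, j) in zip(pairs, truth.pairs):
            d = _min_dist(candidate[idp_atoms_of[pi]],
                          partner_xyz[partner_atoms_of[qj]])
            if d > geo.contact_distance_max + 1e-6:
                return False, (f"planted pair (idp {i}, partner {j}) ended "
                               f"{d:.2f} Å apart, above the "
                               f"{geo.contact_distance_max} Å limit")
        if _min_dist(candidate, partner_xyz) < 2.4:
            return False, "chains interpenetrate (interchain pair < 2.4 Å)"
        return True, ""

    moved = None
    failure = "no docking trial converged"
    centroid_p = partner_xyz.mean(axis=0)
    for trial in range(16):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        start_shift = centroid_p + direction * 25.0 - idp_xyz.mean(axis=0)
        x0 = np.concatenate([rng.normal(scale=1.5, size=3), start_shift])
        res = minimize(cost, x0, method="Powell",
                       options={"maxiter": 4000, "xtol": 1e-3, "ftol": 1e-6})
        candidate = _rigid(res.x, idp_xyz, idp_xyz.mean(axis=0))
        ok, failure = acceptable(candidate)
        if ok:
            moved = candidate
            break
    if moved is None:
        raise PlacementError(failure)

    # assemble the ComplexStructure: IDP chain A, partner chain B
    construct = geo.idp_construct or (1, config.len_idp)
    unresolved = set(geo.unresolved_idp)

    residues: list[ResidueKey] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    atom_res_index: list[int] = []

    def add_residue(chain: str, pos: int, aa: str, xyz, res_of, names,
                    with_atoms: bool) -> None:
        ri = len(residues)
        residues.append(ResidueKey(chain, pos, "", aa))
        if not with_atoms:
            # in the construct but unresolved: residue entry without atoms
            return
        for a in np.where(res_of == pos - 1)[0]:
            name = str(names[a])
            atom_names.append(name)
            elements.append(name[0])  # N/C/O from the leading letter
            coords.append(xyz[a])
            atom_res_index.append(ri)

    for pos in range(1, config.len_idp + 1):
        if not (construct[0] <= pos <= construct[1]):
            continue
        add_residue("A", pos, idp_seq[pos - 1], moved, idp_res_of_atom,
                    idp_atom_name, with_atoms=pos not in unresolved)
    for pos in range(1, config.len_partner + 1):
        add_residue("B", pos, partner_seq[pos - 1], partner_xyz,
                    partner_res_of_atom, partner_atom_name, with_atoms=True)

    nmap = NumberingMap.from_offset({
        "A": (construct[0], construct[1], construct[0]),
        "B": (1, config.len_partner, 1),
    })
    return ComplexStructure(
        residues, atom_names, elements,
        np.asarray(coords, dtype=float).reshape(-1, 3),
        np.asarray(atom_res_index, dtype=int),
        idp_chain="A", partner_chains=["B"], numbering_map=nmap,
    )
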