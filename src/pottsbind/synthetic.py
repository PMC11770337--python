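"""Synthetic test inputs: planted/degenerate/random energy tables, toy
peptide + slab structures, and environment datasets with planted
preferences.

Every generator is a pure function of its spec and seed (byte-identical
reruns), and planted constructions are verified by exhaustive enumeration
at build time whenever the search space is small enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potts import Alphabet, EnergyTables, PottsModel, validate_sequence
from .structure import (AtomRecord, BinningConfig, SideChainEnvironment,
                        SystemConformation)

__all__ = [
    "PlantSpec",
    "DegeneracySpec",
    "make_planted_tables",
    "make_degenerate_tables",
    "make_random_tables",
    "make_toy_system",
    "make_env_dataset",
]

#: fixtures default to a reduced problem so the exhaustive oracle is cheap
SMALL_ALPHABET = Alphabet("ACDEF")


@dataclass
class PlantSpec:
    """A planted-optimum instance: one designated sequence is the unique
    global minimum with a guaranteed margin."""

    n: int = 4
    alphabet: Alphabet = field(default_factory=lambda: SMALL_ALPHABET)
    planted_sequence: str = "ACDE"
    gap: float = 2.0            # score units separating planted letters
    noise_scale: float | None = None   # two-body noise sd; bounded automatically
    lam: float = 0.01           # weight the margin analysis assumes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        validate_sequence(self.planted_sequence, self.alphabet, self.n)


def make_planted_tables(spec: PlantSpec) -> EnergyTables:
    """Tables whose unique optimum is ``spec.planted_sequence``.

    One-body energies are 0 for the planted letter at each position and at
    least gap/n (plus uniform noise < gap/(2n)) for every other letter.
    Two-body entries are zero-mean noise clipped so that, at the assumed
    lambda, the total two-body perturbation of any m-point mutation stays
    below m*gap/(4n); every mutant therefore scores at least 3*gap/(4n)
    per mutated position above the planted sequence.
    """
    rng = np.random.default_rng(spec.seed)
    n, A = spec.n, len(spec.alphabet)
    states = spec.alphabet.encode(spec.planted_sequence)
    one = spec.gap / n + rng.uniform(0.0, spec.gap / (2 * n), size=(n, A))
    one[np.arange(n), states] = 0.0
    bound = spec.gap / (8.0 * max(spec.lam, 1e-12) * n * max(n - 1, 1))
    scale = spec.noise_scale if spec.noise_scale is not None else bound / 3.0
    two = np.zeros((n, n, A, A))
    for i in range(n):
        for j in range(i + 1, n):
            two[i, j] = np.clip(rng.normal(0.0, scale, size=(A, A)), -bound, bound)
    tables = EnergyTables(n=n, alphabet=spec.alphabet, one_body=one,
                          two_body=two, conformation_id=f"planted-seed{spec.seed}")
    if A ** n <= 200_000:
        from .qubo import solve_exhaustive
        best = solve_exhaustive(PottsModel(tables=tables, lam=spec.lam))
        if best.sequence != spec.planted_sequence:
            raise RuntimeError("planted construction failed enumeration check")
    return tables


@dataclass
class DegeneracySpec:
    """An instance with k designated sequences all within ``window`` of the
    optimum and everything else strictly outside the window."""

    n: int = 4
    alphabet: Alphabet = field(default_factory=lambda: SMALL_ALPHABET)
    k_alternates: int = 10
    window: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_alternates < 1:
            raise ValueError("k_alternates must be >= 1")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.k_alternates - 1 > self.n * (len(self.alphabet) - 1):
            raise ValueError("not enough (position, letter) slots for requested k")


def make_degenerate_tables(spec: DegeneracySpec) -> tuple[EnergyTables, list[str]]:
    """Tables with a planted set of near-optimal sequences.

    The base sequence scores 0; k-1 single-position variants have one-body
    excesses spread over (window/2, window]; all other letters cost 4x the
    window.  Because every variant excess exceeds window/2, combining two
    variant letters already exceeds the window, so exactly the planted set
    lies within it (verified by enumeration for small instances).
    """
    rng = np.random.default_rng(spec.seed)
    n, A = spec.n, len(spec.alphabet)
    base_states = rng.integers(0, A, size=n)
    base = spec.alphabet.decode(base_states)
    one = np.full((n, A), 4.0 * spec.window)
    one[np.arange(n), base_states] = 0.0
    planted = [base]
    k = spec.k_alternates
    # cycle positions, assigning distinct non-base letters as variants
    slots = [(i, a) for i in range(n) for a in range(A) if a != base_states[i]]
    rng.shuffle(slots)
    used: set[tuple[int, int]] = set()
    t = 0
    for (i, a) in slots:
        if t >= k - 1:
            break
        if (i, a) in used:
            continue
        used.add((i, a))
        excess = spec.window / 2.0 + spec.window / 2.0 * (t + 1) / (k - 1) if k > 1 else spec.window
        one[i, a] = excess
        planted.append(base[:i] + spec.alphabet.letters[a] + base[i + 1:])
        t += 1
    two = np.zeros((n, n, A, A))
    tables = EnergyTables(n=n, alphabet=spec.alphabet, one_body=one,
                          two_body=two, conformation_id=f"degenerate-seed{spec.seed}")
    if A ** n <= 200_000:
        _verify_degenerate(tables, planted, spec.window)
    return tables, planted


def _verify_degenerate(tables: EnergyTables, planted: list[str], window: float) -> None:
    from itertools import product
    model = PottsModel(tables=tables, lam=0.01)
    from .potts import potts_score
    best = min(potts_score(model, p) for p in planted)
    inside = []
    for combo in product(tables.alphabet.letters, repeat=tables.n):
        seq = "".join(combo)
        if potts_score(model, seq) <= best + window + 1e-9:
            inside.append(seq)
    if sorted(inside) != sorted(planted):
        raise RuntimeError("degenerate construction failed enumeration check")


def make_random_tables(n: int, alphabet: Alphabet, scale: float = 1.0,
                       seed: int = 0) -> EnergyTables:
    """I.i.d. normal one- and two-body energies (mean 0, sd ``scale``)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    A = len(alphabet)
    one = rng.normal(0.0, scale, size=(n, A))
    two = np.zeros((n, n, A, A))
    for i in range(n):
        for j in range(i + 1, n):
            two[i, j] = rng.normal(0.0, scale, size=(A, A))
    return EnergyTables(n=n, alphabet=alphabet, one_body=one, two_body=two,
                        conformation_id=f"random-seed{seed}")


def make_toy_system(n_res: int = 5, slab_nx: int = 8, slab_ny: int = 8,
                    slab_layers: int = 3, spacing: float = 2.5,
                    com_height: float = 4.0, seed: int = 0,
                    with_cb: bool = True) -> SystemConformation:
    """Extended peptide backbone above a rectangular CH2-like lattice slab.

    The peptide runs parallel to the surface with its (geometric) centre of
    mass ``com_height`` Angstrom above the slab top; the slab occupies
    z <= 0 with its top layer exactly at z = 0.
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1
    # --- slab: carbon lattice, top layer at z = 0
    for layer in range(slab_layers):
        z = -1.5 * layer
        for ix in range(slab_nx):
            for iy in range(slab_ny):
                atoms.append(AtomRecord(
                    serial=serial, name="C", residue_index=10_000 + layer,
                    residue_name="PE", segment="plastic",
                    xyz=np.array([ix * spacing, iy * spacing, z]),
                    element="C"))
                serial += 1
    # --- extended backbone along x, alternating pleat in y
    pep: list[AtomRecord] = []
    x0 = (slab_nx - 1) * spacing / 2.0 - 3.8 * (n_res - 1) / 2.0
    y0 = (slab_ny - 1) * spacing / 2.0
    for i in range(n_res):
        flip = 1.0 if i % 2 == 0 else -1.0
        ca = np.array([x0 + 3.8 * i, y0 + 0.3 * flip, 0.0])
        npos = ca + np.array([-1.20, 0.70 * flip, 0.10])
        cpos = ca + np.array([1.25, 0.65 * flip, -0.05])
        opos = cpos + np.array([0.30, 1.15 * flip, 0.35])
        jitter = rng.normal(0.0, 0.01, size=(4, 3))
        for name, xyz, jit in (("N", npos, jitter[0]), ("CA", ca, jitter[1]),
                               ("C", cpos, jitter[2]), ("O", opos, jitter[3])):
            pep.append(AtomRecord(serial=serial, name=name, residue_index=i,
                                  residue_name="ALA" if with_cb else "GLY",
                                  segment="peptide", xyz=xyz + jit, element=name[0]))
            serial += 1
    if with_cb:
        from .structure import virtual_cbeta
        tmp = SystemConformation(atoms + pep)
        for i in range(n_res):
            cb = virtual_cbeta(tmp, i)
            pep.append(AtomRecord(serial=serial, name="CB", residue_index=i,
                                  residue_name="ALA", segment="peptide",
                                  xyz=cb, element="C"))
            serial += 1
    # shift the peptide so its geometric centre sits com_height above z=0
    pep_z = np.mean([a.xyz[2] for a in pep])
    dz = com_height - pep_z
    for a in pep:
        a.xyz = a.xyz + np.array([0.0, 0.0, dz])
    return SystemConformation(atoms + pep)


def make_env_dataset(planted: dict, n_samples: int = 200, seed: int = 0,
                     binning: BinningConfig | None = None,
                     alphabet: Alphabet | None = None,
                     uniform_bins: list | None = None):
    """Environment/amino-acid pairs with planted per-bin preferences.

    ``planted`` maps a bin triple to ``(amino_acid, fraction)``: in that bin
    the amino acid appears in exactly ``round(fraction * n_samples)`` of the
    samples and the rest are drawn uniformly from the remaining letters.
    ``uniform_bins`` lists additional bins populated uniformly (no planted
    preference).
    """
    binning = binning or BinningConfig()
    alphabet = alphabet or Alphabet()
    rng = np.random.default_rng(seed)
    out: list[tuple[SideChainEnvironment, str]] = []

    def sample_descriptor(b: tuple[int, int, int]) -> tuple[float, float, float]:
        def draw(edges, k, cap=12.0):
            lo, hi = edges[k], edges[k + 1]
            lo = -cap if np.isinf(lo) else lo
            hi = cap if np.isinf(hi) else hi
            return rng.uniform(lo, hi)
        d = draw(binning.distance_edges, b[0])
        ang = draw(binning.angle_edges, b[1], cap=180.0)
        sasa = draw(binning.sasa_edges, b[2], cap=150.0)
        return d, ang, max(sasa, 0.0)

    def emit(b, aa):
        d, ang, sasa = sample_descriptor(b)
        env = SideChainEnvironment(residue_index=len(out), distance=d,
                                   angle=ang, sasa=sasa, bin=tuple(b))
        out.append((env, aa))

    for b, (aa, fraction) in planted.items():
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        n_aa = int(round(fraction * n_samples))
        others = [c for c in alphabet.letters if c != aa]
        labels = [aa] * n_aa + [others[int(rng.integers(0, len(others)))]
                                for _ in range(n_samples - n_aa)]
        rng.shuffle(labels)
        for lab in labels:
            emit(b, lab)
    for b in uniform_bins or []:
        for _ in range(n_samples):
            emit(b, alphabet.letters[int(rng.integers(0, len(alphabet)))])
    return out
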