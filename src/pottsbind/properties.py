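"""Physicochemical profiles and statistics for designed peptide sets.

Covers the post-design analyses: Henderson-Hasselbalch net charge and
isoelectric point, molecular mass, a hydropathy/charge solubility proxy
(explicitly NOT CamSol -- see :func:`solubility_proxy`), amino-acid
frequency tables, Welch's unequal-variance t-test for comparing frequency
samples, and the side-chain environment preference table (modal amino acid
per geometric bin, reported only above a one-third frequency threshold).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PKaSet",
    "PropertyProfile",
    "FrequencyTable",
    "EnvironmentPreferenceTable",
    "net_charge",
    "isoelectric_point",
    "molecular_mass",
    "solubility_proxy",
    "property_profile",
    "aa_frequency",
    "welch_t_test",
    "environment_preference",
    "AVERAGE_RESIDUE_MASS",
    "MONOISOTOPIC_RESIDUE_MASS",
    "KYTE_DOOLITTLE",
]


@dataclass(frozen=True)
class PKaSet:
    """Side-chain and terminal pKa values (EMBOSS-style defaults)."""

    acidic: dict = field(default_factory=lambda: {
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1})
    basic: dict = field(default_factory=lambda: {
        "H": 6.5, "K": 10.8, "R": 12.5})
    n_term: float = 8.6
    c_term: float = 3.6


DEFAULT_PKAS = PKaSet()

#: average residue masses, Da (peptide-bond residues; add one water per chain)
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "A": 71.03711, "C": 103.00919, "D": 115.02694, "E": 129.04259,
    "F": 147.06841, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "K": 128.09496, "L": 113.08406, "M": 131.04049, "N": 114.04293,
    "Q": 128.05858, "R": 156.10111, "S": 87.03203, "T": 101.04768,
    "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}
WATER_AVERAGE = 18.0153
WATER_MONO = 18.010565

#: Kyte-Doolittle hydropathy (positive = hydrophobic)
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def net_charge(seq: str, pH: float, pkas: PKaSet = DEFAULT_PKAS) -> float:
    """Henderson-Hasselbalch net charge (e) at ``pH``, termini included."""
    if not (0.0 <= pH <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    for c in seq:
        if c not in AVERAGE_RESIDUE_MASS:
            raise KeyError(f"unknown residue {c!r}")
    pos = [pkas.n_term] + [pkas.basic[c] for c in seq if c in pkas.basic]
    neg = [pkas.c_term] + [pkas.acidic[c] for c in seq if c in pkas.acidic]
    charge = sum(1.0 / (1.0 + 10.0 ** (pH - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pka - pH)) for pka in neg)
    return charge


def isoelectric_point(seq: str, pkas: PKaSet = DEFAULT_PKAS,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes (unique: charge is strictly
    decreasing in pH; the termini guarantee a sign change on [0, 14])."""
    f = lambda ph: net_charge(seq, ph, pkas)
    return float(optimize.brentq(f, 0.0, 14.0, xtol=tol))


def molecular_mass(seq: str, kind: str = "average") -> float:
    """Peptide mass in Da: sum of residue masses plus one water."""
    if kind == "average":
        table, water = AVERAGE_RESIDUE_MASS, WATER_AVERAGE
    elif kind == "monoisotopic":
        table, water = MONOISOTOPIC_RESIDUE_MASS, WATER_MONO
    else:
        raise ValueError("kind must be 'average' or 'monoisotopic'")
    try:
        return sum(table[c] for c in seq) + water
    except KeyError as exc:
        raise KeyError(f"unknown residue {exc.args[0]!r}") from None


def solubility_proxy(seq: str, pkas: PKaSet = DEFAULT_PKAS) -> float:
    """Composition-based solubility score (dimensionless; higher = more
    soluble).

    This is a simple hydropathy/charge proxy -- the negated mean
    Kyte-Doolittle hydropathy plus half the per-residue magnitude of the
    net charge at pH 7.  It is NOT the CamSol intrinsic solubility method
    and is not numerically comparable to CamSol scores.
    """
    if not seq:
        raise ValueError("empty sequence")
    hydro = np.mean([KYTE_DOOLITTLE[c] for c in seq])
    return float(-hydro + 0.5 * abs(net_charge(seq, 7.0, pkas)) / len(seq))


@dataclass
class PropertyProfile:
    sequence: str
    net_charge_ph7: float
    pI: float
    mass: float
    solubility_proxy: float


def property_profile(seq: str, pkas: PKaSet = DEFAULT_PKAS,
                     mass_kind: str = "average") -> PropertyProfile:
    return PropertyProfile(
        sequence=seq,
        net_charge_ph7=net_charge(seq, 7.0, pkas),
        pI=isoelectric_point(seq, pkas),
        mass=molecular_mass(seq, mass_kind),
        solubility_proxy=solubility_proxy(seq, pkas),
    )


@dataclass
class FrequencyTable:
    counts: dict
    total: int

    @property
    def frequencies(self) -> dict:
        return {aa: c / self.total for aa, c in self.counts.items()}


def aa_frequency(seqs) -> FrequencyTable:
    """Per-amino-acid frequency over all residues of a sequence set."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence set")
    counts = Counter()
    for s in seqs:
        counts.update(s)
    total = sum(counts.values())
    return FrequencyTable(counts=dict(counts), total=total)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variance, two-tailed).

    Returns (t, Welch-Satterthwaite df, p).  If both samples have zero
    variance and equal means, returns (0, df, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        df = float(nx + ny - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), df, 0.0
    se2 = vx / nx + vy / ny
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class EnvironmentPreferenceTable:
    """Per geometric bin: the modal amino acid if it clears the one-third
    threshold, else None.  ``entries`` maps bin -> dict with keys
    amino_acid (or None), count, total, tie (bool)."""

    entries: dict
    threshold: float = 1.0 / 3.0


def environment_preference(env_aa_pairs, threshold: float = 1.0 / 3.0
                           ) -> EnvironmentPreferenceTable:
    """Modal amino acid per environment bin from (environment, amino_acid)
    pairs.

    An amino acid is reported only when it occurs in *more than*
    ``threshold`` of the residues in that bin; ties for the mode are
    suppressed (reported as None with a tie flag).
    """
    by_bin: dict = {}
    for env, aa in env_aa_pairs:
        by_bin.setdefault(tuple(env.bin), []).append(aa)
    entries = {}
    for b, aas in by_bin.items():
        counts = Counter(aas)
        total = len(aas)
        (top_aa, top_count), = counts.most_common(1)
        tie = sum(1 for c in counts.values() if c == top_count) > 1
        if not tie and top_count / total > threshold:
            entries[b] = {"amino_acid": top_aa, "count": top_count,
                          "total": total, "tie": False}
        else:
            entries[b] = {"amino_acid": None, "count": top_count,
                          "total": total, "tie": tie}
    return EnvironmentPreferenceTable(entries=entries, threshold=threshold)
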