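"""PIndex: in-silico digestion, inverted-index queries and hyperscore ranking.

A protein FASTA database is digested in silico (trypsin: cleave after K/R
except before P; 1 missed cleavage; length 7-50; charges 1-5; fixed
carbamidomethyl on C; variable oxidation on M and protein N-terminal
acetylation). Each peptide information set S_k holds a unique index k, the
precursor charge and m/z, and the sorted list of singly charged b/y
fragment m/z values.

Two inverted tables answer queries in O(1): the precursor table maps
(m/z bin, charge) -> peptide index set (Index1) and the fragment table
maps m/z bin -> peptide index set (Index2); bin = floor(mz * bins_per_mz)
with +-1 neighbor bins registered so boundary-straddling tolerances stay
covered. A fragment cluster is assigned by intersecting Index1 with the
union of per-fragment Index2 sets and ranking the surviving peptides by
an X!Tandem-style hyperscore:

    hyperscore = log10( Nb! * Ny! * sum(matched intensities) )

where Nb/Ny count matched b/y ions.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from pyteomics import fasta as _pyt_fasta
from pyteomics import parser as _pyt_parser

__all__ = [
    "PeptideEntry", "PeptideMatch", "DigestConfig", "PeptideIndex",
    "MONO_RESIDUE_MASS", "PROTON", "WATER",
    "peptide_mass", "precursor_mz", "fragment_mzs",
    "digest_fasta", "digest_proteins", "build_inverted_index", "hyperscore",
]

# monoisotopic residue masses (Da)
MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
PROTON = 1.007276
WATER = 18.010565
MOD_CARBAMIDOMETHYL = 57.02146  # fixed on C
MOD_OXIDATION = 15.99491        # variable on M
MOD_ACETYL = 42.01057           # variable on protein N-terminus


@dataclass(frozen=True)
class DigestConfig:
    missed_cleavages: int = 1
    min_length: int = 7
    max_length: int = 50
    charges: tuple = (1, 2, 3, 4, 5)
    max_oxidations: int = 1
    nterm_acetyl: bool = True


@dataclass
class PeptideEntry:
    """One in-silico peptide information set S_k."""
    index: int
    sequence: str
    mods: tuple            # e.g. ("ox@3", "acetyl@nterm")
    precursor_charge: int
    precursor_mz: float
    fragment_mzs: np.ndarray   # sorted, b and y interleaved
    b_mzs: np.ndarray
    y_mzs: np.ndarray


@dataclass
class PeptideMatch:
    peptide_index: int
    hyperscore: float
    matched_fragment_ids: list
    n_b: int
    n_y: int


def _residue_masses(sequence: str, oxidized: FrozenSet[int],
                    acetyl: bool) -> np.ndarray:
    m = np.array([MONO_RESIDUE_MASS[a] for a in sequence])
    for i, a in enumerate(sequence):
        if a == "C":
            m[i] += MOD_CARBAMIDOMETHYL
        if i in oxidized:
            m[i] += MOD_OXIDATION
    if acetyl:
        m[0] += MOD_ACETYL
    return m


def peptide_mass(sequence: str, oxidized: Iterable[int] = (),
                 acetyl: bool = False) -> float:
    """Monoisotopic neutral mass with fixed/variable modifications applied."""
    return float(_residue_masses(sequence, frozenset(oxidized), acetyl).sum()
                 + WATER)


def precursor_mz(sequence: str, charge: int, oxidized: Iterable[int] = (),
                 acetyl: bool = False) -> float:
    return (peptide_mass(sequence, oxidized, acetyl) + charge * PROTON) / charge


def fragment_mzs(sequence: str, oxidized: Iterable[int] = (),
                 acetyl: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Singly charged b and y ion m/z arrays (lengths 1..n-1)."""
    m = _residue_masses(sequence, frozenset(oxidized), acetyl)
    prefix = np.cumsum(m)[:-1]
    b = prefix + PROTON
    y = (m.sum() - prefix) + WATER + PROTON
    return b, y


_VALID_SEQ = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def digest_proteins(proteins: Sequence[Tuple[str, str]],
                    rules: DigestConfig = DigestConfig()) -> List[PeptideEntry]:
    """Digest (header, sequence) pairs into peptide entries.

    Deterministic: entries are sorted by (sequence, mods, charge) before
    index assignment, so identical inputs give identical indexes.
    """
    specs = {}  # (sequence, mods) -> is_protein_nterm
    for _, prot in proteins:
        prot = prot.strip().upper().rstrip("*")
        peptides = _pyt_parser.cleave(
            prot, _pyt_parser.expasy_rules["trypsin"],
            missed_cleavages=rules.missed_cleavages)
        for pep in peptides:
            if not rules.min_length <= len(pep) <= rules.max_length:
                continue
            if not _VALID_SEQ.match(pep):
                warnings.warn(f"skipping peptide with nonstandard residue: {pep}")
                continue
            is_nterm = prot.startswith(pep) or prot[1:].startswith(pep)
            key = pep
            specs[key] = specs.get(key, False) or is_nterm
    variants = []
    for pep, is_nterm in specs.items():
        m_pos = [i for i, a in enumerate(pep) if a == "M"]
        ox_choices = [frozenset()]
        if rules.max_oxidations >= 1:
            ox_choices += [frozenset([i]) for i in m_pos]
        if rules.max_oxidations >= 2:
            ox_choices += [frozenset(c) for c in _pairs(m_pos)]
        ac_choices = [False] + ([True] if (rules.nterm_acetyl and is_nterm)
                                else [])
        for ox in ox_choices:
            for ac in ac_choices:
                mods = tuple(sorted(f"ox@{i}" for i in ox)) + \
                    (("acetyl@nterm",) if ac else ())
                variants.append((pep, ox, ac, mods))
    variants.sort(key=lambda v: (v[0], v[3]))
    entries: List[PeptideEntry] = []
    k = 0
    for pep, ox, ac, mods in variants:
        b, y = fragment_mzs(pep, ox, ac)
        frags = np.sort(np.concatenate([b, y]))
        for z in rules.charges:
            entries.append(PeptideEntry(
                index=k, sequence=pep, mods=mods, precursor_charge=z,
                precursor_mz=precursor_mz(pep, z, ox, ac),
                fragment_mzs=frags, b_mzs=b, y_mzs=y))
            k += 1
    return entries


def _pairs(positions):
    return [(a, b) for i, a in enumerate(positions) for b in positions[i + 1:]]


def digest_fasta(path, rules: DigestConfig = DigestConfig()) -> List[PeptideEntry]:
    """In-silico tryptic digestion of a protein FASTA database."""
    proteins = [(h, s) for h, s in _pyt_fasta.read(str(path))]
    return digest_proteins(proteins, rules)


def hyperscore(matched_intensities: Sequence[float], n_b: int, n_y: int) -> float:
    """X!Tandem-style score: log10(Nb! * Ny! * sum I); 0 with no matches."""
    total = float(np.sum(matched_intensities)) if len(matched_intensities) else 0.0
    if total <= 0 or (n_b + n_y) == 0:
        return 0.0
    log10 = (math.lgamma(n_b + 1) + math.lgamma(n_y + 1)) / math.log(10)
    return log10 + math.log10(total)


class PeptideIndex:
    """Inverted precursor/fragment tables over a peptide entry list."""

    def __init__(self, entries: List[PeptideEntry],
                 bins_per_mz: int = 30,
                 precursor_tol_ppm: float = 20.0,
                 fragment_tol_mz: float = 0.03):
        if not entries:
            raise ValueError("empty entry list")
        self.entries = entries
        self.bins_per_mz = bins_per_mz
        self.precursor_tol_ppm = precursor_tol_ppm
        self.fragment_tol_mz = fragment_tol_mz
        self.precursor_table: Dict[Tuple[int, int], Set[int]] = {}
        self.fragment_table: Dict[int, Set[int]] = {}
        for e in entries:
            pb = int(math.floor(e.precursor_mz * bins_per_mz))
            for nb in (pb - 1, pb, pb + 1):
                self.precursor_table.setdefault(
                    (nb, e.precursor_charge), set()).add(e.index)
            for f in e.fragment_mzs:
                fb = int(math.floor(f * bins_per_mz))
                for nb in (fb - 1, fb, fb + 1):
                    self.fragment_table.setdefault(nb, set()).add(e.index)

    # -- queries ----------------------------------------------------------

    def query_precursor(self, mz: float, charge: int) -> Set[int]:
        """Index1: peptides whose precursor matches (mz, charge) in tolerance."""
        if charge < 1:
            raise ValueError("charge must be >= 1")
        b = int(math.floor(mz * self.bins_per_mz))
        cands = self.precursor_table.get((b, charge), set())
        tol = self.precursor_tol_ppm
        return {k for k in cands
                if abs(self.entries[k].precursor_mz - mz)
                / self.entries[k].precursor_mz * 1e6 <= tol}

    def query_fragment(self, mz: float) -> Set[int]:
        """Index2: peptides owning a fragment within tolerance of mz."""
        b = int(math.floor(mz * self.bins_per_mz))
        cands = self.fragment_table.get(b, set())
        tol = self.fragment_tol_mz
        out = set()
        for k in cands:
            f = self.entries[k].fragment_mzs
            i = int(np.searchsorted(f, mz))
            lo = max(0, i - 1)
            if np.min(np.abs(f[lo:i + 1] - mz), initial=np.inf) <= tol:
                out.add(k)
        return out

    # -- cluster assignment ----------------------------------------------

    def _score_entry(self, entry: PeptideEntry, fragments) -> PeptideMatch:
        tol = self.fragment_tol_mz
        matched_ids, intensities = [], []
        n_b = n_y = 0
        for fid, frag in enumerate(fragments):
            db = np.min(np.abs(entry.b_mzs - frag.mz)) if entry.b_mzs.size else np.inf
            dy = np.min(np.abs(entry.y_mzs - frag.mz)) if entry.y_mzs.size else np.inf
            if min(db, dy) > tol:
                continue
            matched_ids.append(fid)
            intensities.append(float(np.max(frag.xic)))
            if db <= dy:
                n_b += 1
            else:
                n_y += 1
        return PeptideMatch(
            peptide_index=entry.index,
            hyperscore=hyperscore(intensities, n_b, n_y),
            matched_fragment_ids=matched_ids, n_b=n_b, n_y=n_y)

    def match_cluster(self, precursor, fragments) -> List[PeptideMatch]:
        """Rank candidate peptides for (precursor, fragment-cluster).

        Candidates are Index1 (precursor query) intersected with the union
        of Index2 over the cluster's fragments; the intersection being a
        subset of both sets is asserted. Empty intersection -> empty list.
        """
        if not len(fragments):
            raise ValueError("empty fragment cluster")
        index1 = self.query_precursor(precursor.mz, precursor.charge)
        if not index1:
            return []
        index2 = set()
        for frag in fragments:
            index2 |= self.query_fragment(frag.mz)
        cands = index1 & index2
        assert cands <= index1 and cands <= index2
        matches = [self._score_entry(self.entries[k], fragments)
                   for k in sorted(cands)]
        matches = [m for m in matches if m.matched_fragment_ids]
        matches.sort(key=lambda m: (-m.hyperscore, m.peptide_index))
        return matches


def build_inverted_index(entries: List[PeptideEntry],
                         bins_per_mz: int = 30, **kw) -> PeptideIndex:
    return PeptideIndex(entries, bins_per_mz=bins_per_mz, **kw)
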