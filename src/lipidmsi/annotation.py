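"""Accurate-mass annotation and cross-modal Level-2 identification.

The annotation path mirrors common imaging-lipidomics practice: imaging
features are putatively annotated by accurate-mass search (default tolerance
0.05 Da) against an enumerated combinatorial lipid database under the common
positive/negative adducts, then confirmed by class-diagnostic MS2 fragments
from a surface-extraction run.  A species identified by both modalities under
the *same adduct* is reported at identification Level 2 of the Lipidomics
Standards Initiative scale (species-level: no double-bond or sn-position
resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ADDUCTS,
    CO2_MASS,
    NH3_MASS,
    PROTON_MASS,
    WATER_MASS,
    AdductSpec,
    LipidRecord,
    acyl_mass,
    adduct_mz,
    normalize_adduct_name,
    parse_shorthand,
    ppm_deviation,
)

__all__ = [
    "AnnotationHit",
    "MS2Spectrum",
    "MS2Match",
    "Level2Record",
    "LipidDatabase",
    "build_database",
    "default_database",
    "accurate_mass_search",
    "fragment_rules",
    "enumerate_acyl_decompositions",
    "match_ms2",
    "level2_crossmatch",
    "replay_table1_crossmatch",
    "PHOSPHOCHOLINE_FRAGMENT",
]

# Protonated phosphocholine head group C5H15NO4P+, the hallmark positive-mode
# PC fragment.
PHOSPHOCHOLINE_FRAGMENT = 184.07332

_NEGATIVE_ADDUCTS = tuple(a for a in ADDUCTS.values() if a.polarity == "negative")
_POSITIVE_ADDUCTS = tuple(a for a in ADDUCTS.values() if a.polarity == "positive")


@dataclass(frozen=True)
class AnnotationHit:
    """One (lipid, adduct) explanation of an observed m/z."""

    query_mz: float
    lipid: LipidRecord
    adduct: AdductSpec
    theoretical_mz: float
    delta_da: float
    delta_ppm: float


@dataclass
class MS2Spectrum:
    """A centroided fragmentation spectrum."""

    precursor_mz: float
    polarity: str
    fragments: list[tuple[float, float]]

    def __post_init__(self):
        for mz, inten in self.fragments:
            if mz >= self.precursor_mz + 1.0:
                raise ValueError(
                    f"fragment m/z {mz} above precursor isolation window")
            if inten < 0:
                raise ValueError("negative fragment intensity")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.fragments], dtype=float)


@dataclass(frozen=True)
class MS2Match:
    hit: AnnotationHit
    matched_fragments: int
    rule_fragments: int


@dataclass(frozen=True)
class Level2Record:
    """Cross-modal species identification (same lipid, same adduct)."""

    feature_id: object
    lipid_name: str
    adduct_name: str
    desi_evidence: object = None
    lesa_evidence: object = None


class UnsupportedClassError(ValueError):
    """Raised when no fragment rule exists for a class/adduct combination."""


@dataclass
class LipidDatabase:
    """Enumerated lipid records with precomputed adduct m/z per polarity."""

    records: list[LipidRecord]
    adduct_mz_table: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.adduct_mz_table:
            masses = np.array([r.monoisotopic_mass for r in self.records])
            self.adduct_mz_table = {
                name: masses + spec.mass_shift for name, spec in ADDUCTS.items()
            }

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, shorthand: str) -> bool:
        want = parse_shorthand(shorthand).species_name
        return any(r.species_name == want for r in self.records)


def build_database(
    class_grid: Sequence[tuple[str, tuple[int, int], tuple[int, int], tuple[int, int]]],
) -> LipidDatabase:
    """Enumerate a combinatorial lipid database.

    Parameters
    ----------
    class_grid
        Entries ``(lipid_class, (c_min, c_max), (d_min, d_max), (x_min, x_max))``
        spanning total acyl carbons, double bonds and extra oxygens.  The
        enumeration is deterministic (class order, then carbons, double
        bonds, oxygens).
    """
    if not class_grid:
        raise ValueError("empty class grid")
    records: list[LipidRecord] = []
    for cls, (c0, c1), (d0, d1), (x0, x1) in class_grid:
        for c in range(c0, c1 + 1):
            for d in range(d0, d1 + 1):
                if 2 * c - 2 * d <= 0:
                    continue
                for x in range(x0, x1 + 1):
                    ox = "" if x == 0 else (";O" if x == 1 else f";O{x}")
                    records.append(parse_shorthand(f"{cls}({c}:{d}{ox})"))
    return LipidDatabase(records)


def default_database() -> LipidDatabase:
    """Default grid covering the DESI-observable neutral lipid space.

    Spans free (and singly oxidized) fatty acids, di-/triacylglycerols,
    diacyl phospholipids and lysophospholipids with even-to-odd chain totals
    typical of vertebrate tissue.
    """
    return build_database([
        ("FA", (12, 24), (0, 6), (0, 1)),
        ("DG", (24, 40), (0, 8), (0, 0)),
        ("TG", (40, 60), (0, 10), (0, 0)),
        ("PC", (28, 44), (0, 10), (0, 0)),
        ("PE", (28, 44), (0, 10), (0, 0)),
        ("PEe", (28, 44), (0, 10), (0, 0)),
        ("PI", (28, 44), (0, 10), (0, 0)),
        ("PG", (28, 40), (0, 8), (0, 0)),
        ("PS", (28, 40), (0, 8), (0, 0)),
        ("LPC", (12, 24), (0, 6), (0, 0)),
        ("LPE", (12, 24), (0, 6), (0, 0)),
    ])


def accurate_mass_search(
    query_mz: float,
    polarity: str,
    database: LipidDatabase,
    tol_da: float = 0.05,
) -> list[AnnotationHit]:
    """All (lipid, adduct) pairs within ``tol_da`` of ``query_mz``.

    Hits are sorted by absolute ppm deviation; ties break by lipid class
    name, then total carbons.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    adducts = _POSITIVE_ADDUCTS if polarity == "positive" else _NEGATIVE_ADDUCTS
    hits: list[AnnotationHit] = []
    for spec in adducts:
        theo = database.adduct_mz_table[spec.name]
        idx = np.nonzero(np.abs(theo - query_mz) <= tol_da)[0]
        for i in idx:
            t = float(theo[i])
            hits.append(AnnotationHit(
                query_mz=query_mz,
                lipid=database.records[i],
                adduct=spec,
                theoretical_mz=t,
                delta_da=query_mz - t,
                delta_ppm=ppm_deviation(query_mz, t),
            ))
    hits.sort(key=lambda h: (abs(h.delta_ppm), h.lipid.lipid_class,
                             h.lipid.total_carbons))
    return hits


# Acyl chains commonly seen in vertebrate lipids; used to propose chain
# decompositions when only a species-level annotation is available.
COMMON_ACYLS: tuple[tuple[int, int], ...] = (
    (12, 0), (14, 0), (14, 1), (16, 0), (16, 1), (17, 0), (17, 1),
    (18, 0), (18, 1), (18, 2), (18, 3), (20, 0), (20, 1), (20, 3),
    (20, 4), (20, 5), (22, 5), (22, 6),
)

_CHAIN_COUNT = {
    "FA": 1, "LPC": 1, "LPE": 1, "LPG": 1, "LPS": 1,
    "DG": 2, "PC": 2, "PE": 2, "PEe": 2, "PI": 2, "PG": 2, "PA": 2, "PS": 2,
    "TG": 3,
}


def enumerate_acyl_decompositions(
    total_carbons: int, total_double_bonds: int, n_chains: int,
    pool: Iterable[tuple[int, int]] = COMMON_ACYLS,
) -> list[tuple[tuple[int, int], ...]]:
    """Chain multisets from ``pool`` summing to the species totals."""
    out = []
    for combo in combinations_with_replacement(sorted(pool), n_chains):
        if (sum(c for c, _ in combo) == total_carbons
                and sum(d for _, d in combo) == total_double_bonds):
            out.append(combo)
    return out


def _chains_of(lipid: LipidRecord) -> list[tuple[int, int, int]] | None:
    if lipid.chains:
        return list(lipid.chains)
    if _CHAIN_COUNT.get(lipid.lipid_class) == 1:
        return [(lipid.total_carbons, lipid.total_double_bonds,
                 lipid.oxygen_extra)]
    return None


def fragment_rules(
    lipid: LipidRecord,
    adduct: AdductSpec | str,
    chains: Sequence[tuple[int, int] | tuple[int, int, int]] | None = None,
) -> list[float]:
    """Class-diagnostic fragment m/z values for a lipid under an adduct.

    Rules (all singly charged):

    * ``FA`` / ``[M-H]-`` — water loss and CO2 loss from the precursor.
    * ``TG`` / ``[M+Na]+`` — neutral loss of each distinct acyl as the free
      acid; under ``[M+NH4]+`` the loss additionally sheds NH3.
    * ``DG`` / ``[M+H-H2O]+`` — loss of each distinct acyl (free acid),
      leaving the complementary monoacyl fragment.
    * ``PC`` positive — the protonated phosphocholine head group 184.0733.
    * ``PE``/``PEe``/``PI``/``PG``/``PS``/``LPE`` negative — the fatty acyl
      carboxylate anion of each chain.

    Chain-resolved rules need an acyl composition, either stored on the
    record, passed via ``chains``, or implied (single-chain classes).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[normalize_adduct_name(adduct)]
    cls = lipid.lipid_class
    prec = adduct_mz(lipid.monoisotopic_mass, adduct)

    if cls == "FA" and adduct.name == "[M-H]-":
        return [prec - WATER_MASS, prec - CO2_MASS]

    if cls == "PC" and adduct.polarity == "positive":
        return [PHOSPHOCHOLINE_FRAGMENT]

    chain_list: list[tuple[int, int, int]] | None
    if chains is not None:
        chain_list = [(c[0], c[1], c[2] if len(c) > 2 else 0) for c in chains]
    else:
        chain_list = _chains_of(lipid)

    if cls == "TG" and adduct.name in ("[M+Na]+", "[M+NH4]+"):
        if chain_list is None:
            raise ValueError(f"acyl composition required for {lipid.species_name}")
        losses = sorted({acyl_mass(c, d, x) for c, d, x in chain_list})
        if adduct.name == "[M+NH4]+":
            return [prec - m - NH3_MASS for m in losses]
        return [prec - m for m in losses]

    if cls == "DG" and adduct.name == "[M+H-H2O]+":
        if chain_list is None:
            raise ValueError(f"acyl composition required for {lipid.species_name}")
        losses = sorted({acyl_mass(c, d, x) for c, d, x in chain_list})
        return [prec - m for m in losses]

    if cls in ("PE", "PEe", "PI", "PG", "PS", "LPE") and adduct.polarity == "negative":
        if chain_list is None:
            raise ValueError(f"acyl composition required for {lipid.species_name}")
        return sorted({acyl_mass(c, d, x) - PROTON_MASS for c, d, x in chain_list})

    raise UnsupportedClassError(
        f"no fragment rule for {cls} under {adduct.name}")


def _candidate_fragment_sets(hit: AnnotationHit) -> list[list[float]]:
    """Rule fragments for a hit; enumerate chain splits when unresolved."""
    lipid, adduct = hit.lipid, hit.adduct
    try:
        return [fragment_rules(lipid, adduct)]
    except UnsupportedClassError:
        return []
    except ValueError:
        pass  # needs a chain decomposition
    n = _CHAIN_COUNT.get(lipid.lipid_class)
    if n is None:
        return []
    decomps = enumerate_acyl_decompositions(
        lipid.total_carbons, lipid.total_double_bonds, n)
    sets = []
    for decomp in decomps:
        try:
            sets.append(fragment_rules(lipid, adduct, chains=decomp))
        except (ValueError, UnsupportedClassError):
            continue
    return sets


def match_ms2(
    spectrum: MS2Spectrum,
    candidates: Sequence[AnnotationHit],
    tol_ppm: float = 5.0,
    isolation_window_da: float = 0.5,
) -> MS2Match | None:
    """Score candidates by matched class-diagnostic fragments.

    Candidates whose theoretical precursor falls outside the isolation
    window, or that match zero rule fragments, are rejected.  The best match
    has the most matched fragments; ties break by precursor ppm deviation.
    """
    peaks = spectrum.mz_array
    best: MS2Match | None = None
    for hit in candidates:
        if abs(spectrum.precursor_mz - hit.theoretical_mz) > isolation_window_da:
            continue
        top = (0, 0)
        for frags in _candidate_fragment_sets(hit):
            if not frags:
                continue
            matched = sum(
                1 for f in frags
                if peaks.size and np.min(np.abs(peaks - f)) <= f * tol_ppm * 1e-6
            )
            if matched > top[0]:
                top = (matched, len(frags))
        if top[0] == 0:
            continue
        cand = MS2Match(hit, top[0], top[1])
        if (best is None
                or cand.matched_fragments > best.matched_fragments
                or (cand.matched_fragments == best.matched_fragments
                    and abs(cand.hit.delta_ppm) < abs(best.hit.delta_ppm))):
            best = cand
    return best


def level2_crossmatch(
    desi_hits: Sequence[tuple[object, AnnotationHit]],
    lesa_ids: Sequence[tuple[LipidRecord, str, object]],
) -> list[Level2Record]:
    """Cross-modal identification: same lipid species AND same adduct.

    ``desi_hits`` pairs a feature id with an imaging annotation hit;
    ``lesa_ids`` lists surface-extraction identifications as
    ``(lipid, adduct_name, ms2_evidence)``.  One record is emitted per
    (feature, lipid, adduct) combination present on both sides.
    """
    lesa_index: dict[tuple[str, str], object] = {}
    for lipid, adduct_name, evidence in lesa_ids:
        key = (lipid.species_name, normalize_adduct_name(adduct_name))
        lesa_index.setdefault(key, evidence)
    records: list[Level2Record] = []
    seen: set[tuple[object, str, str]] = set()
    for feature_id, hit in desi_hits:
        key = (hit.lipid.species_name, hit.adduct.name)
        if key not in lesa_index:
            continue
        tag = (feature_id, *key)
        if tag in seen:
            continue
        seen.add(tag)
        records.append(Level2Record(
            feature_id=feature_id,
            lipid_name=key[0],
            adduct_name=key[1],
            desi_evidence=hit,
            lesa_evidence=lesa_index[key],
        ))
    return records


def replay_table1_crossmatch(records) -> list[Level2Record]:
    """Apply the same-lipid/same-adduct rule to curated summary records.

    Each record contributes its primary imaging adduct on the DESI side and
    its primary extraction adduct on the LESA side; a Level-2 record results
    when they agree for the same annotation.
    """
    desi = []
    lesa = []
    for i, rec in enumerate(records):
        lipid = parse_shorthand(rec.annotation)
        spec = ADDUCTS[normalize_adduct_name(rec.desi_adduct)]
        theo = adduct_mz(lipid.monoisotopic_mass, spec)
        desi.append((i, AnnotationHit(
            query_mz=rec.desi_avg_mz, lipid=lipid, adduct=spec,
            theoretical_mz=theo, delta_da=rec.desi_avg_mz - theo,
            delta_ppm=ppm_deviation(rec.desi_avg_mz, theo))))
        lesa.append((lipid, rec.lesa_adduct, rec.lesa_observed_ms1))
    return level2_crossmatch(desi, lesa)
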