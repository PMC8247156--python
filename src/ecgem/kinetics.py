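"""Kinetic (kcat) and abundance evidence tables and their selection rules.

Turnover numbers come from curated database extracts: either direct kcat
measurements (1/h) or specific activities (SA, µmol/(mg·min)) together with
a molecular weight, which convert as ``kcat = SA · MW · 60 · 1e3 · 1e-6``.
When several measurements exist for one protein/reaction pair the maximum
direct kcat wins; SA-derived values are used only when no direct kcat is
reported.

Abundances come from proteomics compendia and may be measured in a related
organism rather than the target species.  Matching walks the taxonomy
outwards — species, genus, family, order, class — and takes the maximum
abundance at the first rank where any record exists; proteins with no match
at any rank are left unconstrained downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "RANKS",
    "KcatRecord",
    "AbundanceRecord",
    "KineticTable",
    "AbundanceTable",
    "sa_to_kcat",
    "select_kcat",
    "match_abundance",
    "ppm_to_mmol_per_gdw",
    "read_kcat_tsv",
    "read_abundance_tsv",
    "read_taxonomy_tsv",
]

#: Taxonomic ranks searched for homologous abundance, nearest first.
RANKS: Tuple[str, ...] = ("species", "genus", "family", "order", "class")

WILDCARD = "*"


@dataclass(frozen=True)
class KcatRecord:
    """One piece of turnover-number evidence for a protein (and reaction)."""

    protein: str
    reaction: str = WILDCARD  # wildcard: applies to every catalyzed reaction
    kcat: Optional[float] = None  # 1/h
    sa: Optional[float] = None  # µmol/(mg·min)
    mw: Optional[float] = None  # g/mol
    source: str = ""

    def __post_init__(self) -> None:
        if self.kcat is None and (self.sa is None or self.mw is None):
            raise ValueError(
                f"{self.protein}/{self.reaction}: need kcat or (sa and mw)"
            )
        for name in ("kcat", "sa", "mw"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.protein}: {name} must be > 0, got {v}")

    @property
    def effective_kcat(self) -> float:
        """Direct kcat if present, else the SA conversion."""
        if self.kcat is not None:
            return self.kcat
        return sa_to_kcat(self.sa, self.mw)

    @property
    def is_direct(self) -> bool:
        return self.kcat is not None


@dataclass(frozen=True)
class AbundanceRecord:
    """Protein abundance evidence with taxonomic provenance."""

    protein: str
    abundance: float  # mmol/gDW (canonical internal unit)
    taxon: str = ""
    rank: str = "species"

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"{self.protein}: abundance must be >= 0")
        if self.rank not in RANKS:
            raise ValueError(f"{self.protein}: unknown rank {self.rank!r}")


def sa_to_kcat(sa: float, mw: float) -> float:
    """Convert a specific activity to a turnover number.

    Parameters
    ----------
    sa : specific activity, µmol/(mg·min)
    mw : molecular weight, g/mol (Da)

    Returns
    -------
    kcat in 1/h: ``SA · MW · 60 min/h · 1e3 mg/g · 1e-6 mol/µmol``
    (net factor 0.06·SA·MW).
    """
    if sa <= 0 or mw <= 0:
        raise ValueError(f"sa and mw must be > 0 (got sa={sa}, mw={mw})")
    return sa * mw * 60.0 * 1e3 * 1e-6


@dataclass(frozen=True)
class KcatSelection:
    kcat: float  # 1/h
    rule: str  # "BRENDA-max" | "SA-derived"
    record: KcatRecord


def select_kcat(records: Sequence[KcatRecord]) -> KcatSelection:
    """Pick the kcat for one protein/reaction from competing evidence.

    The maximum over *direct* kcat entries wins; SA-derived values are a
    fallback used only when no direct measurement exists.  The result is
    invariant under permutation of ``records`` (ties broken by value, then
    source string, for determinism).
    """
    records = list(records)
    if not records:
        raise ValueError("no kinetic evidence")
    direct = [r for r in records if r.is_direct]
    pool = direct if direct else records
    best = max(pool, key=lambda r: (r.effective_kcat, r.source, r.protein))
    rule = "BRENDA-max" if direct else "SA-derived"
    return KcatSelection(best.effective_kcat, rule, best)


class KineticTable:
    """kcat evidence indexed by (protein, reaction).

    Reaction-specific records beat wildcard records; within a group the
    :func:`select_kcat` rule applies.
    """

    def __init__(self, records: Iterable[KcatRecord] = ()) -> None:
        self._groups: Dict[Tuple[str, str], List[KcatRecord]] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: KcatRecord) -> None:
        self._groups.setdefault((rec.protein, rec.reaction), []).append(rec)

    def __len__(self) -> int:
        return sum(len(v) for v in self._groups.values())

    @property
    def proteins(self) -> List[str]:
        return sorted({p for p, _ in self._groups})

    def lookup(self, protein: str, reaction: str) -> Optional[KcatSelection]:
        """Resolved kcat for a protein catalyzing a reaction, or None."""
        group = self._groups.get((protein, reaction))
        if group is None:
            group = self._groups.get((protein, WILDCARD))
        if not group:
            return None
        return select_kcat(group)

    def mw(self, protein: str) -> Optional[float]:
        """Any recorded molecular weight for the protein (max if several)."""
        mws = [r.mw for (p, _), recs in self._groups.items() if p == protein
               for r in recs if r.mw is not None]
        return max(mws) if mws else None


def match_abundance(
    protein: str,
    records: Sequence[AbundanceRecord],
    taxonomy: Optional[Mapping[str, str]] = None,
) -> Optional[AbundanceRecord]:
    """Resolve the abundance bound for a protein by taxonomic proximity.

    ``taxonomy`` maps taxon name -> rank relative to the target organism
    (overriding each record's own ``rank`` tag when present).  Records at the
    nearest rank with any entry are considered and the maximum abundance
    among them is returned; ``None`` means no evidence at any rank, and the
    enzyme is left unconstrained.
    """
    mine = [r for r in records if r.protein == protein]
    by_rank: Dict[str, List[AbundanceRecord]] = {}
    for rec in mine:
        rank = rec.rank
        if taxonomy is not None and rec.taxon:
            if rec.taxon not in taxonomy:
                warnings.warn(
                    f"abundance record for {protein}: unknown taxon "
                    f"{rec.taxon!r}, skipped",
                    stacklevel=2,
                )
                continue
            rank = taxonomy[rec.taxon]
        if rank != rec.rank:  # carry the resolved rank in the result
            rec = AbundanceRecord(rec.protein, rec.abundance, rec.taxon, rank)
        by_rank.setdefault(rank, []).append(rec)
    for rank in RANKS:
        pool = by_rank.get(rank)
        if pool:
            return max(pool, key=lambda r: (r.abundance, r.taxon))
    return None


class AbundanceTable:
    """Abundance evidence indexed by protein."""

    def __init__(
        self,
        records: Iterable[AbundanceRecord] = (),
        taxonomy: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.records: List[AbundanceRecord] = list(records)
        self.taxonomy = dict(taxonomy) if taxonomy is not None else None

    def add(self, rec: AbundanceRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, protein: str) -> Optional[AbundanceRecord]:
        return match_abundance(protein, self.records, self.taxonomy)

    def bound(self, protein: str) -> float:
        """Usage upper bound in mmol/gDW (+inf when no evidence matches)."""
        rec = self.lookup(protein)
        return rec.abundance if rec is not None else math.inf


def ppm_to_mmol_per_gdw(ppm: float, mw: float, ptot: float = 0.5) -> float:
    """Convert a PAXdb-style ppm abundance to mmol protein per gDW.

    ``ppm`` is parts of the protein per million parts of total protein (by
    mass); ``mw`` in g/mol; ``ptot`` the total protein content of biomass in
    g protein/gDW (default 0.5).  Then

        abundance [mmol/gDW] = ppm·1e-6 · ptot / MW · 1e3
    """
    if mw <= 0 or ptot <= 0:
        raise ValueError("mw and ptot must be > 0")
    return ppm * 1e-6 * ptot / mw * 1e3


# ---------------------------------------------------------------------------
# TSV ingestion
# ---------------------------------------------------------------------------


def read_kcat_tsv(path: str) -> KineticTable:
    """Read a kcat evidence table.

    Columns: ``protein``, ``reaction`` (empty or ``*`` = wildcard),
    ``kcat_per_h``, ``sa``, ``mw_da``, ``source`` (the last four optional
    per-row, subject to the KcatRecord invariant).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "reaction": str})
    table = KineticTable()
    for row in df.itertuples(index=False):
        def get(name):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v
        reaction = get("reaction") or WILDCARD
        table.add(KcatRecord(
            protein=str(row.protein),
            reaction=str(reaction),
            kcat=None if get("kcat_per_h") is None else float(get("kcat_per_h")),
            sa=None if get("sa") is None else float(get("sa")),
            mw=None if get("mw_da") is None else float(get("mw_da")),
            source=str(get("source") or ""),
        ))
    return table


def read_abundance_tsv(
    path: str,
    taxonomy: Optional[Mapping[str, str]] = None,
    ptot: float = 0.5,
    mw_lookup: Optional[Mapping[str, float]] = None,
) -> AbundanceTable:
    """Read an abundance table.

    Columns: ``protein``, ``abundance``, ``unit`` (``mmol_per_gdw`` or
    ``ppm``), ``taxon``, ``rank``.  ppm rows need a molecular weight via
    ``mw_lookup`` and are converted with :func:`ppm_to_mmol_per_gdw`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        protein = str(row.protein)
        value = float(row.abundance)
        unit = (getattr(row, "unit", None) or "mmol_per_gdw").strip()
        if unit == "ppm":
            if mw_lookup is None or protein not in mw_lookup:
                warnings.warn(
                    f"ppm abundance for {protein} without MW: skipped",
                    stacklevel=2,
                )
                continue
            value = ppm_to_mmol_per_gdw(value, mw_lookup[protein], ptot)
        elif unit != "mmol_per_gdw":
            raise ValueError(f"unknown abundance unit {unit!r} for {protein}")
        rank = getattr(row, "rank", None) or "species"
        taxon = getattr(row, "taxon", None) or ""
        records.append(AbundanceRecord(protein, value, str(taxon), str(rank)))
    return AbundanceTable(records, taxonomy)


def read_taxonomy_tsv(path: str) -> Dict[str, str]:
    """Read a taxon -> rank mapping (columns ``taxon``, ``rank``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, str] = {}
    for row in df.itertuples(index=False):
        rank = str(row.rank)
        if rank not in RANKS:
            raise ValueError(f"taxonomy {path}: unknown rank {rank!r}")
        out[str(row.taxon)] = rank
    return out
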