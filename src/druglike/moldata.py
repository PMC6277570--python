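"""SDF reading and chemical dataset cleaning.

Raw vendor datasets (drug-like and non-drug-like compound collections in
2D V2000 SDF) are curated before descriptor calculation:

1. **element filter** — hydrocarbons (heavy atoms are carbon only) are
   removed, as are molecules containing any element outside
   C H O N P S Cl Br I Si;
2. **mixture removal** — records whose structure has more than one
   connected component (salts, solvates, true mixtures) are removed;
3. **deduplication** — molecules are identified by their standard InChI
   including the stereochemistry layer; within a set, only the first
   occurrence of an InChI is kept, and any InChI present in both the
   positive and negative sets is removed from the negative set only.

The order above is a fixed convention of this package.  A pluggable
``normalizer`` hook runs between mixture removal and deduplication; the
default is a no-op.  (The original workflow standardised structures with
a commercial tool — neutralise, tautomerise, aromatise, clean 2D; no
open equivalent is bundled, so this is a documented fidelity gap unless
the caller supplies their own normaliser.)

Unparseable SDF entries are counted and skipped, not fatal: bulk SDF
files routinely contain broken records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

from rdkit import Chem, RDLogger

from .errors import DataError

ALLOWED_ELEMENTS = frozenset({"C", "H", "O", "N", "P", "S", "Cl", "Br", "I", "Si"})


@dataclass
class MoleculeRecord:
    """One structure with provenance and a canonical identifier."""

    record_id: int  # ordinal within the source file
    mol: Chem.Mol
    canonical_id: str  # standard InChI, stereochemistry included
    source_set: str  # {"positive", "negative"}


@dataclass
class CleaningReport:
    """Per-rule removal counts for one cleaning run over both sets.

    ``input_count`` equals ``output_count`` plus all removals plus
    ``parse_failures``.
    """

    input_count: int = 0
    output_count: int = 0
    parse_failures: int = 0
    removed_hydrocarbon: int = 0
    removed_element: int = 0
    removed_mixture: int = 0
    removed_duplicate_within: int = 0
    removed_cross_set: int = 0

    def reconciles(self) -> bool:
        removed = (self.removed_hydrocarbon + self.removed_element
                   + self.removed_mixture + self.removed_duplicate_within
                   + self.removed_cross_set)
        return self.input_count == self.output_count + removed + self.parse_failures

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _inchi(mol: Chem.Mol) -> str:
    RDLogger.DisableLog("rdApp.*")
    try:
        return Chem.MolToInchi(mol) or ""
    finally:
        RDLogger.EnableLog("rdApp.error")


def read_sdf(path: str | Path, source_set: str = "positive") -> tuple[list[MoleculeRecord], int]:
    """Read an SDF file into records; returns ``(records, parse_failures)``.

    One record per ``$$$$``-delimited entry.  Entries RDKit cannot parse
    or sanitise are counted as parse failures and skipped.  A missing
    file, or a file yielding zero parseable records, is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"SDF file not found: {path}")
    RDLogger.DisableLog("rdApp.*")
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        records, failures = [], 0
        for ordinal, mol in enumerate(supplier):
            if mol is None:
                failures += 1
                continue
            records.append(MoleculeRecord(
                record_id=ordinal, mol=mol,
                canonical_id=_inchi(mol), source_set=source_set,
            ))
    finally:
        RDLogger.EnableLog("rdApp.error")
    if not records:
        raise DataError(f"no parseable molecules in {path}")
    return records, failures


def element_filter(records: Sequence[MoleculeRecord]) -> tuple[list, list, list]:
    """Split records into (kept, removed_hydrocarbon, removed_element).

    Hydrocarbons are molecules whose heavy-atom element set is a subset
    of {C} (hydrogens ignored); everything containing an element outside
    the whitelist is likewise removed.  Input order is preserved.
    """
    kept, hydrocarbons, bad_element = [], [], []
    for rec in records:
        symbols = {atom.GetSymbol() for atom in rec.mol.GetAtoms()}
        heavy = symbols - {"H"}
        if heavy <= {"C"}:
            hydrocarbons.append(rec)
        elif not symbols <= ALLOWED_ELEMENTS:
            bad_element.append(rec)
        else:
            kept.append(rec)
    return kept, hydrocarbons, bad_element


def remove_mixtures(records: Sequence[MoleculeRecord]) -> tuple[list, list]:
    """Remove records whose bond graph has more than one connected component.

    Salts and solvates count as mixtures; no fragment is kept.  Each
    record is counted once however many fragments it contains.
    """
    kept, removed = [], []
    for rec in records:
        n_frags = len(Chem.GetMolFrags(rec.mol))
        (removed if n_frags > 1 else kept).append(rec)
    return kept, removed


def deduplicate(
    positive: Sequence[MoleculeRecord],
    negative: Sequence[MoleculeRecord],
) -> tuple[list, list, int, int]:
    """InChI-based deduplication within and across the two sets.

    Within each set only the first occurrence of a canonical id is kept
    (input order).  Any id present in both sets is dropped from the
    negative set only.  Returns
    ``(positive_out, negative_out, n_within, n_cross)``.
    """
    def first_occurrences(records):
        seen, out, dropped = set(), [], 0
        for rec in records:
            if not rec.canonical_id:
                rec.canonical_id = _inchi(rec.mol)
            if rec.canonical_id in seen:
                dropped += 1
            else:
                seen.add(rec.canonical_id)
                out.append(rec)
        return out, dropped

    pos_out, pos_dropped = first_occurrences(positive)
    neg_out, neg_dropped = first_occurrences(negative)
    pos_ids = {rec.canonical_id for rec in pos_out}
    cross = [rec for rec in neg_out if rec.canonical_id in pos_ids]
    neg_out = [rec for rec in neg_out if rec.canonical_id not in pos_ids]

    if not pos_out:
        raise DataError("positive set is empty after deduplication")
    if not neg_out:
        raise DataError("negative set is empty after deduplication")
    return pos_out, neg_out, pos_dropped + neg_dropped, len(cross)


def clean(
    positive: Sequence[MoleculeRecord],
    negative: Sequence[MoleculeRecord],
    parse_failures: int = 0,
    normalizer: Callable[[Chem.Mol], Chem.Mol] | None = None,
) -> tuple[list, list, CleaningReport]:
    """Run the full cleaning pipeline over both sets.

    Rule order: element filter -> mixture removal -> (optional
    normaliser) -> deduplication.  The pipeline is idempotent: cleaning
    its own output removes nothing further.
    """
    report = CleaningReport(input_count=len(positive) + len(negative) + parse_failures,
                            parse_failures=parse_failures)

    pos, pos_hc, pos_el = element_filter(positive)
    neg, neg_hc, neg_el = element_filter(negative)
    report.removed_hydrocarbon = len(pos_hc) + len(neg_hc)
    report.removed_element = len(pos_el) + len(neg_el)

    pos, pos_mix = remove_mixtures(pos)
    neg, neg_mix = remove_mixtures(neg)
    report.removed_mixture = len(pos_mix) + len(neg_mix)

    if normalizer is not None:
        for rec in [*pos, *neg]:
            rec.mol = normalizer(rec.mol)
            rec.canonical_id = _inchi(rec.mol)

    pos, neg, n_within, n_cross = deduplicate(pos, neg)
    report.removed_duplicate_within = n_within
    report.removed_cross_set = n_cross
    report.output_count = len(pos) + len(neg)
    return pos, neg, report


def write_sdf(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records back to a V2000 SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            writer.write(rec.mol)
    finally:
        writer.close()
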