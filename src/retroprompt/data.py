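"""Reaction dataset ingestion, canonicalization, tokenization, cleaning and splitting.

A reaction is represented as a :class:`ReactionRecord`: a set of precursor
molecules (reactants merged with reagents) on the left and a single product
on the right, optionally carrying a dotted reaction-class code
(e.g. ``"6.1.2"``, whose leading integer is the superclass).

The cleaning pipeline applies, in a fixed order, the standard text-mined
reaction-corpus filters: drop unparsable reactions, canonicalize, make
precursors a set, strip residual precursor molecules from the product side
and drop remaining multi-product reactions, drop products introducing
elements absent from the precursors, drop single-atom products, drop
reactions with excessive net formal charge, drop over-long token sequences,
drop duplicates, and drop precursor sets mapping to conflicting products.
Each removal is attributed to the first rule that fires, so the counts in
the :class:`CleaningReport` sum exactly to the number of records removed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger

from .errors import (
    ConfigError,
    InvalidMoleculeError,
    ReactionParseError,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")

# SMILES token grammar: bracket atoms, two-letter halogens, aromatic and
# organic-subset atoms, ring-closure escapes %NN, and every single
# structural character. Pinned as one constant; round-trip is tested.
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|/|:"
    r"|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_TOKEN_RE = re.compile(SMILES_TOKEN_PATTERN)

MAX_TOKENS_PER_SIDE = 500
MAX_ABS_FORMAL_CHARGE = 2


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: precursors (reactants + reagents) and a single product."""

    id: str
    precursors: tuple[str, ...]
    product: str
    class_code: str | None = None
    token: int | None = None

    @property
    def superclass(self) -> int | None:
        """Leading integer of the dotted class code, if present."""
        if self.class_code is None:
            return None
        head = self.class_code.split(".", 1)[0]
        return int(head) if head.lstrip("-").isdigit() else None

    def reaction_smiles(self) -> str:
        return f"{'.'.join(self.precursors)}>>{self.product}"


@dataclass
class CleaningReport:
    """Per-rule removal counts for one cleaning run."""

    counts_removed_per_rule: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def add(self, rule: str) -> None:
        self.counts_removed_per_rule[rule] = self.counts_removed_per_rule.get(rule, 0) + 1

    @property
    def n_removed(self) -> int:
        return sum(self.counts_removed_per_rule.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                "counts_removed_per_rule": self.counts_removed_per_rule,
            },
            indent=2,
        )


@dataclass
class DatasetSplit:
    train: list[ReactionRecord]
    validation: list[ReactionRecord]
    test: list[ReactionRecord]
    seed: int
    fractions: tuple[float, float, float]


def parse_reaction(line: str, id: str = "") -> ReactionRecord:
    """Parse one reaction SMILES line into a record.

    Accepts ``reactants>reagents>product`` and ``precursors>>product``;
    reactant and reagent groups are merged into the precursor list. The
    two-group dialect ``reactants>product`` is accepted as reagent-free.
    """
    stripped = line.strip()
    groups = stripped.split(">")
    if len(groups) == 3:
        reactants, reagents, product = groups
    elif len(groups) == 2:
        reactants, product = groups
        reagents = ""
    else:
        raise ReactionParseError(
            f"expected 2 or 3 '>'-separated groups, got {len(groups)}: {line!r}"
        )
    if not reactants or not product:
        raise ReactionParseError(f"empty reactant or product group: {line!r}")
    precursors = [s for g in (reactants, reagents) for s in g.split(".") if s]
    return ReactionRecord(id=id, precursors=tuple(precursors), product=product)


@lru_cache(maxsize=262144)
def canonicalize(smiles: str) -> str:
    """Canonical SMILES of a single molecule; idempotent by construction.

    Memoized: the same molecules recur thousands of times across cleaning
    and metric computations.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def canonical_precursor_set(precursors: Iterable[str]) -> tuple[str, ...]:
    """Sorted tuple of unique canonical SMILES — the package-wide set key."""
    return tuple(sorted({canonicalize(s) for s in precursors}))


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into model tokens.

    The concatenation of the returned tokens reproduces the input exactly;
    multi-character atoms (Cl, Br, bracket atoms) are single tokens.
    """
    tokens = _TOKEN_RE.findall(smiles)
    joined = "".join(tokens)
    if joined != smiles:
        # locate the first offending character for the error message
        pos = 0
        for tok in tokens:
            if smiles[pos : pos + len(tok)] != tok:
                break
            pos += len(tok)
        raise TokenizationError(
            f"untokenizable span at position {pos}: {smiles[pos:pos + 8]!r} in {smiles!r}"
        )
    return tokens


def _mols(smiles_list: Sequence[str]) -> list[Chem.Mol] | None:
    mols = [Chem.MolFromSmiles(s) for s in smiles_list]
    return None if any(m is None for m in mols) else mols


def _elements(mols: Iterable[Chem.Mol]) -> set[str]:
    return {a.GetSymbol() for m in mols for a in m.GetAtoms()}


def clean_dataset(
    records: Iterable[ReactionRecord],
) -> tuple[list[ReactionRecord], CleaningReport]:
    """Apply the full cleaning pipeline; returns survivors and a report.

    Rules, in firing order (first match attributes the removal):

    1. ``invalid``: any molecule unparsable (canonicalization happens here);
    2. precursor set semantics (transform, no removal);
    3. residual precursor molecules removed from the product side, then
       ``multi_product``: more (or fewer) than one product remains;
    4. ``atoms_not_in_precursors``: product element absent from precursors;
    5. ``single_atom``: single-atom product;
    6. ``charge``: |net formal charge| of either side exceeds 2;
    7. ``token_length``: either side tokenizes to more than 500 tokens;
    8. ``duplicates``: exact duplicate of an earlier surviving reaction;
    9. ``same_precursors_different_products``: all members of a group
       sharing a precursor set but with conflicting products.

    The pipeline is idempotent: cleaning its own output removes nothing.
    """
    records = list(records)
    report = CleaningReport(n_input=len(records))
    survivors: list[ReactionRecord] = []

    for rec in records:
        prec_mols = _mols(rec.precursors)
        prod_mols = _mols(rec.product.split("."))
        if prec_mols is None or prod_mols is None or not rec.precursors or not rec.product:
            report.add("invalid")
            continue
        precursors = canonical_precursor_set(rec.precursors)
        products = [Chem.MolToSmiles(m) for m in prod_mols]

        # residual precursor molecules on the product side, then multi-product
        products = [p for p in products if p not in set(precursors)]
        if len(products) != 1:
            report.add("multi_product")
            continue
        product = products[0]
        product_mol = Chem.MolFromSmiles(product)

        prec_mols = [Chem.MolFromSmiles(s) for s in precursors]
        if not _elements([product_mol]) <= _elements(prec_mols):
            report.add("atoms_not_in_precursors")
            continue
        if product_mol.GetNumAtoms() == 1:
            report.add("single_atom")
            continue
        prec_charge = sum(Chem.GetFormalCharge(m) for m in prec_mols)
        prod_charge = Chem.GetFormalCharge(product_mol)
        if abs(prec_charge) > MAX_ABS_FORMAL_CHARGE or abs(prod_charge) > MAX_ABS_FORMAL_CHARGE:
            report.add("charge")
            continue
        if (
            len(tokenize_smiles(".".join(precursors))) > MAX_TOKENS_PER_SIDE
            or len(tokenize_smiles(product)) > MAX_TOKENS_PER_SIDE
        ):
            report.add("token_length")
            continue
        survivors.append(replace(rec, precursors=precursors, product=product))

    # exact duplicates (same canonical precursor set and product)
    seen: set[tuple[tuple[str, ...], str]] = set()
    deduped: list[ReactionRecord] = []
    for rec in survivors:
        key = (rec.precursors, rec.product)
        if key in seen:
            report.add("duplicates")
        else:
            seen.add(key)
            deduped.append(rec)

    # conflicting products for one precursor set: drop the whole group
    products_by_precursors: dict[tuple[str, ...], set[str]] = {}
    for rec in deduped:
        products_by_precursors.setdefault(rec.precursors, set()).add(rec.product)
    final: list[ReactionRecord] = []
    for rec in deduped:
        if len(products_by_precursors[rec.precursors]) > 1:
            report.add("same_precursors_different_products")
        else:
            final.append(rec)

    report.n_output = len(final)
    return final, report


def split_dataset(
    records: Sequence[ReactionRecord],
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetSplit:
    """Random train/validation/test split, deterministic given ``seed``.

    Validation and test sizes are floors of their fractions; the remainder
    goes to train, preserving the stated test/validation proportions.
    """
    import numpy as np

    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fractions}")
    if not records:
        raise ConfigError("cannot split an empty dataset")
    n = len(records)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    order = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in order[: n - n_val - n_test]]
    val = [records[i] for i in order[n - n_val - n_test : n - n_test]]
    test = [records[i] for i in order[n - n_test :]]
    if n_val == 0 or n_test == 0:
        warnings.warn(
            f"split of {n} records with fractions {fractions} leaves an empty "
            "validation or test set",
            stacklevel=2,
        )
    return DatasetSplit(train=train, validation=val, test=test, seed=seed, fractions=fractions)


def read_reactions(
    path: str | Path, class_path: str | Path | None = None
) -> list[ReactionRecord]:
    """Read a reaction file (one reaction SMILES per line), optionally with a
    line-aligned class file (one dotted code per line)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    classes: list[str | None]
    if class_path is not None:
        classes = [ln.strip() for ln in Path(class_path).read_text().splitlines() if ln.strip()]
        if len(classes) != len(lines):
            raise ReactionParseError(
                f"class file has {len(classes)} lines but reaction file has {len(lines)}"
            )
    else:
        classes = [None] * len(lines)
    records = []
    for i, (line, cls) in enumerate(zip(lines, classes)):
        rec = parse_reaction(line, id=str(i))
        records.append(replace(rec, class_code=cls))
    return records


def write_reactions(
    records: Iterable[ReactionRecord],
    path: str | Path,
    class_path: str | Path | None = None,
) -> None:
    """Write records as ``precursors>>product`` lines (+ optional class file)."""
    records = list(records)
    Path(path).write_text("".join(r.reaction_smiles() + "\n" for r in records))
    if class_path is not None:
        Path(class_path).write_text(
            "".join((r.class_code or "") + "\n" for r in records)
        )


def write_cleaning_report(report: CleaningReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n")


def records_from_mapping(
    rows: Iterable[Mapping[str, object]],
) -> list[ReactionRecord]:
    """Build records from dict-like rows with keys id/precursors/product/class_code."""
    return [
        ReactionRecord(
            id=str(r.get("id", i)),
            precursors=tuple(r["precursors"]),  # type: ignore[arg-type]
            product=str(r["product"]),
            class_code=(str(r["class_code"]) if r.get("class_code") is not None else None),
        )
        for i, r in enumerate(rows)
    ]
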