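"""Miniature template chemistry: synthetic reaction corpus and oracle models.

The toy world contains linear molecules only: unbranched chains of alkyl
segments joined by functional-group linkers. Six template families are
defined, each with a distinct linker and a coupling rule:

==  ============  ===========  =================================
id  family        linker       precursor pair
==  ============  ===========  =================================
0   ester         C(=O)O       carboxylic acid + alcohol
1   amide         C(=O)N       carboxylic acid + amine
2   ether         O            alcohol + alkyl bromide
3   thioether     S            thiol + alkyl bromide
4   amine         N            amine + alkyl bromide
5   thioester     C(=O)S       carboxylic acid + thiol
==  ============  ===========  =================================

Because each product can carry several linkers from different families, a
single target admits several class-distinct disconnections — exactly the
situation in which conditioning a retrosynthesis model on a class token
pays off. Three deterministic oracles close the evaluation loop without
any neural model:

* :func:`oracle_retro` — splits the product at the linkers of the family
  named by the prompt token (an inapplicable token yields a deliberately
  invalid guess: the product itself);
* :func:`baseline_retro` — always disconnects the lowest-indexed
  applicable family, emulating the majority-class bias of an
  unconditioned model;
* :func:`oracle_forward` / :func:`oracle_classify` — recombine a
  precursor pair into its product / name the family that does so.

All edits are string templates over guaranteed-valid linear SMILES; the
molecule graph (via RDKit) is only used to recover the linear form from an
arbitrary (e.g. canonicalized) spelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .data import ReactionRecord, canonicalize
from .errors import ConfigError
from .prompting import parse_source

NO_REACTION = "NO_REACTION"  # sentinel; never a valid product SMILES
NO_CLASS = -1


@dataclass(frozen=True)
class TemplateFamily:
    fid: int
    name: str
    linker: str  # SMILES infix between the two alkyl-terminated fragments
    roles: frozenset[str]  # precursor-role pair identifying the family


FAMILIES: tuple[TemplateFamily, ...] = (
    TemplateFamily(0, "ester", "C(=O)O", frozenset({"acid", "alcohol"})),
    TemplateFamily(1, "amide", "C(=O)N", frozenset({"acid", "amine"})),
    TemplateFamily(2, "ether", "O", frozenset({"alcohol", "bromide"})),
    TemplateFamily(3, "thioether", "S", frozenset({"thiol", "bromide"})),
    TemplateFamily(4, "amine", "N", frozenset({"amine", "bromide"})),
    TemplateFamily(5, "thioester", "C(=O)S", frozenset({"acid", "thiol"})),
)

_FAMILY_BY_ROLES = {f.roles: f for f in FAMILIES}


# ---------------------------------------------------------------------------
# linear-molecule parsing

_ALLOWED = {"C", "N", "O", "S", "Br"}


def _toy_backbone(smiles: str) -> list[tuple[str, bool]] | None:
    """Ordered backbone of a toy molecule as (symbol, is_carbonyl_carbon).

    Returns None if the molecule is outside the toy grammar (rings,
    branches, charges, disallowed elements, multiple fragments). The
    backbone is returned in the primary orientation: of the two possible
    end-to-end readings, the one whose emitted SMILES is lexicographically
    smaller.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or "." in smiles or mol.GetRingInfo().NumRings() > 0:
        return None
    carbonyl_o: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _ALLOWED or atom.GetFormalCharge() != 0:
            return None
        if atom.GetIsAromatic():
            return None
        if atom.GetSymbol() == "O" and atom.GetDegree() == 1:
            bond = atom.GetBonds()[0]
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                if bond.GetOtherAtom(atom).GetSymbol() != "C":
                    return None
                carbonyl_o.add(atom.GetIdx())
    # every remaining bond must be single and connect backbone atoms
    backbone = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in carbonyl_o]
    adj: dict[int, list[int]] = {i: [] for i in backbone}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in carbonyl_o or j in carbonyl_o:
            continue
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return None
        adj[i].append(j)
        adj[j].append(i)
    if not backbone:
        return None
    ends = [i for i in backbone if len(adj[i]) <= 1]
    if any(len(adj[i]) > 2 for i in backbone):
        return None
    if len(backbone) == 1:
        path = backbone
    else:
        if len(ends) != 2:
            return None
        path = [ends[0]]
        while len(path) < len(backbone):
            prev = path[-2] if len(path) >= 2 else None
            nxt = [n for n in adj[path[-1]] if n != prev]
            if len(nxt) != 1:
                return None
            path.append(nxt[0])

    def describe(idx: int) -> tuple[str, bool]:
        atom = mol.GetAtomWithIdx(idx)
        sym = atom.GetSymbol()
        is_carbonyl = sym == "C" and any(
            n.GetIdx() in carbonyl_o for n in atom.GetNeighbors()
        )
        return (sym, is_carbonyl)

    seq = [describe(i) for i in path]
    # carbonyl carbons may carry exactly one =O and two backbone neighbours
    for (sym, carb), idx in zip(seq, path):
        n_carbonyl = sum(
            1 for n in mol.GetAtomWithIdx(idx).GetNeighbors() if n.GetIdx() in carbonyl_o
        )
        if n_carbonyl > 1 or (n_carbonyl == 1 and sym != "C"):
            return None
        if sym == "Br" and mol.GetAtomWithIdx(idx).GetDegree() != 1:
            return None
    fwd = _emit(seq)
    rev = _emit(seq[::-1])
    return seq if fwd <= rev else seq[::-1]


def _emit(seq: Sequence[tuple[str, bool]]) -> str:
    return "".join("C(=O)" if carb else sym for sym, carb in seq)


def linearize(smiles: str) -> str | None:
    """Primary linear SMILES of a toy molecule, or None if not a toy molecule."""
    seq = _toy_backbone(smiles)
    return None if seq is None else _emit(seq)


# ---------------------------------------------------------------------------
# disconnection sites


@dataclass(frozen=True)
class _Site:
    family: TemplateFamily
    position: int  # backbone index, for left-to-right ordering
    precursors: tuple[str, str]


_PAIR_FAMILY = {"O": FAMILIES[0], "N": FAMILIES[1], "S": FAMILIES[5]}
_SINGLE_FAMILY = {"O": FAMILIES[2], "S": FAMILIES[3], "N": FAMILIES[4]}


def _sites(seq: Sequence[tuple[str, bool]]) -> list[_Site]:
    """All disconnection sites of a backbone, left to right."""
    n = len(seq)
    sites: list[_Site] = []
    for i in range(n):
        sym, carb = seq[i]
        if carb and i + 1 < n:
            nxt_sym, nxt_carb = seq[i + 1]
            if not nxt_carb and nxt_sym in _PAIR_FAMILY:
                # acyl linkage read as C(=O)X: left acid, X starts the partner
                if i >= 1 and i + 2 <= n - 1:
                    fam = _PAIR_FAMILY[nxt_sym]
                    acid = _emit(seq[: i + 1]) + "O"
                    partner = _emit(seq[i + 1 :])
                    sites.append(_Site(fam, i, (acid, partner)))
        if not carb and sym in _PAIR_FAMILY and i + 1 < n and seq[i + 1][1]:
            # reversed acyl linkage X-C(=O): left partner, right acid
            if i >= 1 and i + 2 <= n - 1:
                fam = _PAIR_FAMILY[sym]
                partner = _emit(seq[: i + 1])
                acid = "O" + _emit(seq[i + 1 :])
                sites.append(_Site(fam, i, (partner, acid)))
        if not carb and sym in _SINGLE_FAMILY and 0 < i < n - 1:
            left_sym, left_carb = seq[i - 1]
            right_sym, right_carb = seq[i + 1]
            if left_sym == "C" and right_sym == "C" and not left_carb and not right_carb:
                fam = _SINGLE_FAMILY[sym]
                left = _emit(seq[: i + 1])  # keeps the heteroatom
                right = "Br" + _emit(seq[i + 1 :])
                sites.append(_Site(fam, i, (left, right)))
    sites.sort(key=lambda s: s.position)
    return sites


def disconnection_sites(product: str) -> list[_Site]:
    seq = _toy_backbone(product)
    return [] if seq is None else _sites(seq)


def applicable_families(product: str) -> list[int]:
    """Sorted family ids with at least one disconnection site in ``product``."""
    return sorted({s.family.fid for s in disconnection_sites(product)})


# ---------------------------------------------------------------------------
# oracle models


def _role(seq: Sequence[tuple[str, bool]]) -> tuple[str, list[tuple[str, bool]]] | None:
    """Functional role of a toy precursor, with the backbone oriented so the
    functional end comes last (``Br`` first for bromides)."""
    if len(seq) < 2:
        return None

    def end_role(terminal: tuple[str, bool], neighbor: tuple[str, bool]) -> str | None:
        sym, carb = terminal
        if sym == "O" and not carb:
            return "acid" if neighbor[1] else "alcohol"
        if sym == "N" and not carb:
            return None if neighbor[1] else "amine"
        if sym == "S" and not carb:
            return None if neighbor[1] else "thiol"
        if sym == "Br":
            return "bromide"
        return None

    first = end_role(seq[0], seq[1])
    last = end_role(seq[-1], seq[-2])
    if (first is None) == (last is None):
        return None  # zero or two functional ends: not a toy precursor
    if first is not None:
        oriented = list(seq[::-1])
        role = first
    else:
        oriented = list(seq)
        role = last
    if role == "bromide":
        oriented = oriented[::-1]  # Br first
    return role, oriented


def oracle_forward(precursors: Iterable[str]) -> str:
    """Couple a precursor pair into its product, or ``NO_REACTION``.

    The set must contain exactly two distinct molecules whose functional
    roles match exactly one family's precursor-pair pattern; anything else
    (including a single molecule, i.e. the invalid guess) yields
    ``NO_REACTION``.
    """
    product_and_family = _forward_with_family(precursors)
    return NO_REACTION if product_and_family is None else product_and_family[0]


def _forward_with_family(precursors: Iterable[str]) -> tuple[str, int] | None:
    unique: dict[str, str] = {}
    for s in precursors:
        try:
            unique[canonicalize(s)] = s
        except Exception:
            return None
    if len(unique) != 2:
        return None
    parsed = []
    for s in unique.values():
        seq = _toy_backbone(s)
        if seq is None:
            return None
        role = _role(seq)
        if role is None:
            return None
        parsed.append(role)
    roles = frozenset(r for r, _ in parsed)
    family = _FAMILY_BY_ROLES.get(roles)
    if family is None or len(roles) != 2:
        return None
    by_role = {r: seq for r, seq in parsed}
    if "acid" in by_role:
        acid = _emit(by_role["acid"])  # ends with C(=O)O
        partner_role = next(r for r in roles if r != "acid")
        partner = _emit(by_role[partner_role][::-1])  # functional atom first
        product = acid[:-1] + partner  # drop the acid OH; partner donates O/N/S
    else:
        nucleophile_role = next(r for r in roles if r != "bromide")
        nucleophile = _emit(by_role[nucleophile_role])  # ends with O/N/S
        bromide = _emit(by_role["bromide"])  # starts with Br
        product = nucleophile + bromide[2:]
    return product, family.fid


def oracle_retro(source: str, n: int) -> list[tuple[str, ...]]:
    """Up to ``n`` disconnections of the prompted product for the prompt's family.

    The source line carries the cluster token and the tokenized product. If
    the token's family has no linker in the product, a single deliberately
    invalid guess — the product itself — is returned (the forward oracle
    rejects single-molecule "reactions").
    """
    token, product = parse_source(source)
    splits = [
        s.precursors for s in disconnection_sites(product) if s.family.fid == token
    ]
    if not splits:
        return [(product,)]
    return [tuple(p) for p in splits[:n]]


def baseline_retro(product: str, n: int) -> list[tuple[str, ...]]:
    """Unconditioned model stand-in with a majority-class bias.

    Always disconnects using the lowest-indexed applicable family only,
    cycling through that family's sites to produce ``n`` near-duplicate
    predictions; a product with no linker yields invalid guesses.
    """
    sites = disconnection_sites(product)
    fams = sorted({s.family.fid for s in sites})
    if not fams:
        return [(product,)] * n
    chosen = fams[0]
    splits = [tuple(s.precursors) for s in sites if s.family.fid == chosen]
    return [splits[i % len(splits)] for i in range(n)]


def oracle_classify(precursors: Iterable[str], product: str) -> int:
    """Family whose forward rule maps ``precursors`` to ``product``; else ``NO_CLASS``."""
    result = _forward_with_family(precursors)
    if result is None:
        return NO_CLASS
    forward_product, fid = result
    try:
        if canonicalize(forward_product) == canonicalize(product):
            return fid
    except Exception:
        return NO_CLASS
    return NO_CLASS


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class ToyDatasetParams:
    """Conditions of the synthetic corpus.

    ``weights`` are the class-imbalance weights over the ``n_families``
    families (uniform when None); each product carries between
    ``groups_per_product[0]`` and ``groups_per_product[1]`` linkers, with
    alkyl segments of ``chain_length`` carbons between them; the recorded
    reaction forms one linker whose family is sampled by the weights.
    """

    n_reactions: int = 500
    n_families: int = 4
    chain_length: tuple[int, int] = (1, 3)
    groups_per_product: tuple[int, int] = (1, 3)
    weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_families <= len(FAMILIES):
            raise ConfigError(
                f"n_families must be in 1-{len(FAMILIES)}, got {self.n_families}"
            )
        if self.chain_length[0] < 1 or self.chain_length[0] > self.chain_length[1]:
            raise ConfigError(f"invalid chain_length range {self.chain_length}")
        if self.groups_per_product[0] < 1 or (
            self.groups_per_product[0] > self.groups_per_product[1]
        ):
            raise ConfigError(f"invalid groups_per_product range {self.groups_per_product}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.n_families or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    "weights must be non-negative, one per family, and sum to 1"
                )


def generate_dataset(params: ToyDatasetParams) -> list[ReactionRecord]:
    """Deterministic synthetic reaction corpus.

    Each product is a linear chain of alkyl segments joined by sampled
    family linkers; the recorded reaction is the first disconnection site
    of the sampled (weights-biased) family, so the target precursors equal
    the conditioned top-1 prediction for that family's token.
    """
    rng = np.random.default_rng(params.seed)
    t = params.n_families
    weights = (
        np.full(t, 1.0 / t) if params.weights is None else np.asarray(params.weights)
    )
    lo_g, hi_g = params.groups_per_product
    lo_c, hi_c = params.chain_length
    records: list[ReactionRecord] = []
    for i in range(params.n_reactions):
        g = int(rng.integers(lo_g, hi_g + 1))
        recorded = int(rng.choice(t, p=weights))
        fams = [recorded] + [int(rng.choice(t, p=weights)) for _ in range(g - 1)]
        order = rng.permutation(g)
        fams = [fams[j] for j in order]
        seg_lengths = rng.integers(lo_c, hi_c + 1, size=g + 1)
        product = "C" * int(seg_lengths[0])
        for fam, seg in zip(fams, seg_lengths[1:]):
            product += FAMILIES[fam].linker + "C" * int(seg)
        splits = [
            s.precursors
            for s in disconnection_sites(product)
            if s.family.fid == recorded
        ]
        records.append(
            ReactionRecord(
                id=f"toy-{i}",
                precursors=tuple(splits[0]),
                product=product,
                class_code=str(recorded),
            )
        )
    return records
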