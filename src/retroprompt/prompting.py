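"""Token-prepended training pairs, inference fan-out, and prediction merging.

Training: the cluster token ``[i]`` is prepended, as its own
whitespace-delimited vocabulary item, to the tokenized product SMILES; the
target is the tokenized "."-joined canonical precursor set.

Inference: a product is fanned out into X copies, one per token, and the
ranked per-token predictions are merged rank-major (all conditioned top-1
predictions first, then all top-2, ...), so the first X entries of the
merged list are exactly the X conditioned top-1s. With topk predictions
kept per token, the merged list has up to X * topk entries (the "topN").
Duplicate predictions across tokens are kept; the diversity metrics
collapse them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .data import ReactionRecord, canonical_precursor_set, tokenize_smiles
from .errors import ConfigError, DataError, InvalidMoleculeError

_PROMPT_RE = re.compile(r"^\[(\d+)\]$")


@dataclass(frozen=True)
class PromptedSample:
    """A conditioned source line and its (possibly empty) target line."""

    source: str
    target: str = ""


@dataclass
class MergedPredictionList:
    """Merged per-token predictions: (token, rank-within-token, precursors SMILES)."""

    entries: list[tuple[int, int, str]]
    topk: int
    x: int

    @property
    def predictions(self) -> list[str]:
        return [smiles for _, _, smiles in self.entries]


def prompt_token(token: int) -> str:
    return f"[{token}]"


def build_training_pair(record: ReactionRecord) -> PromptedSample:
    """Source ``"[t] <tokenized product>"``; target the tokenized precursors.

    Precursors are emitted as the "."-join of their sorted canonical forms,
    so any input ordering yields the same target.
    """
    if record.token is None:
        raise DataError(f"record {record.id} has no assigned token")
    source = prompt_token(record.token) + " " + " ".join(tokenize_smiles(record.product))
    target = " ".join(tokenize_smiles(".".join(canonical_precursor_set(record.precursors))))
    return PromptedSample(source=source, target=target)


def fan_out(product: str, x: int) -> list[str]:
    """The X conditioned source lines for one product, tokens 0..X-1."""
    if x < 1:
        raise ConfigError(f"x must be >= 1, got {x}")
    from rdkit import Chem

    if Chem.MolFromSmiles(product) is None:
        raise InvalidMoleculeError(f"unparsable product SMILES: {product!r}")
    body = " ".join(tokenize_smiles(product))
    return [f"{prompt_token(i)} {body}" for i in range(x)]


def parse_source(source: str) -> tuple[int, str]:
    """Invert the prompted-source framing: ``(token, product SMILES)``."""
    head, _, rest = source.partition(" ")
    m = _PROMPT_RE.match(head)
    if not m:
        raise DataError(f"source does not start with a cluster token: {source!r}")
    return int(m.group(1)), rest.replace(" ", "")


def merge_predictions(
    per_token: Mapping[int, Sequence[str]], topk: int
) -> MergedPredictionList:
    """Merge ranked per-token prediction lists, keeping topk per token.

    Ordering is rank-major then token-minor: every token's rank-1
    prediction (in token order) precedes any rank-2 prediction. Tokens with
    fewer than topk predictions contribute what they have; duplicates are
    retained.
    """
    if topk < 1:
        raise ConfigError(f"topk must be >= 1, got {topk}")
    tokens = sorted(per_token)
    entries: list[tuple[int, int, str]] = []
    for rank in range(topk):
        for token in tokens:
            preds = per_token[token]
            if rank < len(preds):
                entries.append((token, rank, preds[rank]))
    return MergedPredictionList(entries=entries, topk=topk, x=len(tokens))


# ---------------------------------------------------------------------------
# line-aligned src/tgt files (standard seq2seq text interchange)


def write_src_tgt(
    samples: Sequence[PromptedSample],
    src_path: str | Path,
    tgt_path: str | Path | None = None,
) -> None:
    Path(src_path).write_text("".join(s.source + "\n" for s in samples))
    if tgt_path is not None:
        Path(tgt_path).write_text("".join(s.target + "\n" for s in samples))


def read_src_tgt(
    src_path: str | Path, tgt_path: str | Path | None = None
) -> list[PromptedSample]:
    sources = Path(src_path).read_text().splitlines()
    if tgt_path is None:
        return [PromptedSample(source=s) for s in sources]
    targets = Path(tgt_path).read_text().splitlines()
    if len(sources) != len(targets):
        raise DataError(
            f"src has {len(sources)} lines but tgt has {len(targets)}"
        )
    return [PromptedSample(source=s, target=t) for s, t in zip(sources, targets)]


def write_manifest(
    path: str | Path, x: int, topk: int, scheme_id: str, extra: dict | None = None
) -> None:
    payload = {"x": x, "topk": topk, "scheme_id": scheme_id}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
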