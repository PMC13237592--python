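"""Pluggable sequence -> fixed-width vector providers.

The production backend is the frozen ProtT5 encoder
(``prot_t5_xl_half_uniref50-enc``, 1024-wide) with mean pooling over
per-residue states — the standard per-protein protocol for that model.
The synthetic provider implements the same pooling contract over
deterministic pseudo-embeddings so the whole pipeline is testable without
model weights or downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from sublyme.io_formats import ALLOWED_RESIDUES, EmbeddingStore, ProteinRecord

__all__ = [
    "EmbeddingProvider",
    "ProviderUnavailableError",
    "synthetic_provider",
    "plm_provider",
    "embed_sequences",
]

PROTT5_DIM = 1024
DEFAULT_PLM_MODEL = "Rostlab/prot_t5_xl_half_uniref50-enc"


class ProviderUnavailableError(RuntimeError):
    """The requested embedding backend cannot run in this environment."""


@dataclass
class EmbeddingProvider:
    """A named, deterministic sequence -> vector function.

    ``residue_states`` maps a sequence to an (L, dim) array of per-residue
    states; the per-protein vector is their mean (mean pooling).  A provider
    may set ``max_length`` to truncate long sequences before embedding; the
    default is no truncation.
    """

    name: str
    dimensionality: int
    residue_states: Callable[[str], np.ndarray]
    max_length: int | None = None

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        if self.max_length is not None:
            sequence = sequence[: self.max_length]
        states = np.asarray(self.residue_states(sequence), dtype=np.float32)
        if states.ndim != 2 or states.shape != (len(sequence), self.dimensionality):
            raise ValueError(
                f"provider {self.name!r} returned states of shape "
                f"{states.shape}, expected ({len(sequence)}, {self.dimensionality})"
            )
        return states.mean(axis=0)


def synthetic_provider(dimensionality: int = 32, seed: int = 0) -> EmbeddingProvider:
    """Deterministic hash-free pseudo-embedder for tests and simulations.

    Each amino-acid letter is assigned a fixed random state vector drawn
    once from a seeded generator; the per-residue state depends only on the
    letter, so mean pooling of a homopolymer returns that letter's state
    exactly (the pooling-linearity contract).
    """
    rng = np.random.default_rng(seed)
    letters = sorted(ALLOWED_RESIDUES)
    table = {
        aa: rng.standard_normal(dimensionality).astype(np.float32) for aa in letters
    }

    def residue_states(sequence: str) -> np.ndarray:
        return np.stack([table[aa] for aa in sequence])

    return EmbeddingProvider(
        name=f"synthetic-d{dimensionality}-s{seed}",
        dimensionality=dimensionality,
        residue_states=residue_states,
    )


def plm_provider(
    model_name: str = DEFAULT_PLM_MODEL, max_length: int | None = None
) -> EmbeddingProvider:
    """Frozen protein-language-model backend (ProtT5 encoder, 1024-wide).

    Requires the optional ``torch``/``transformers`` stack and locally
    available weights; anything missing raises ``ProviderUnavailableError``
    — never a silent fallback to another provider.
    """
    try:
        import torch  # noqa: F401
        from transformers import T5EncoderModel, T5Tokenizer
    except ImportError as exc:
        raise ProviderUnavailableError(
            f"provider unavailable: the ProtT5 backend needs torch and "
            f"transformers installed ({exc})"
        ) from exc

    try:
        tokenizer = T5Tokenizer.from_pretrained(model_name, local_files_only=True)
        model = T5EncoderModel.from_pretrained(model_name, local_files_only=True)
    except Exception as exc:  # weights absent / cache miss
        raise ProviderUnavailableError(
            f"provider unavailable: model weights for {model_name!r} are not "
            f"locally available ({exc})"
        ) from exc
    model.eval()

    def residue_states(sequence: str) -> np.ndarray:
        import torch

        spaced = " ".join(sequence)
        tokens = tokenizer(spaced, return_tensors="pt", add_special_tokens=True)
        with torch.no_grad():
            out = model(**tokens).last_hidden_state[0]
        # drop the trailing special token; keep one state per residue
        return out[: len(sequence)].float().cpu().numpy()

    return EmbeddingProvider(
        name=model_name,
        dimensionality=PROTT5_DIM,
        residue_states=residue_states,
        max_length=max_length,
    )


def embed_sequences(
    provider: EmbeddingProvider, proteins: Iterable[ProteinRecord]
) -> EmbeddingStore:
    """Embed every protein; one mean-pooled vector per id.

    Sequences containing letters outside the accepted residue alphabet
    raise an error naming the protein.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in proteins:
        bad = sorted(set(rec.sequence) - ALLOWED_RESIDUES)
        if bad:
            raise ValueError(
                f"protein {rec.id!r} contains illegal residue letters: "
                f"{''.join(bad)}"
            )
        ids.append(rec.id)
        rows.append(provider.embed(rec.sequence))
    vectors = (
        np.stack(rows)
        if rows
        else np.empty((0, provider.dimensionality), dtype=np.float32)
    )
    return EmbeddingStore(ids, vectors, provider=provider.name)
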