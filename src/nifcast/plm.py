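"""Optional adapter for a real protein language model backend.

Fulfils the :class:`nifcast.sequence_features.EmbeddingBackend`
contract by calling a public encoder-style model (ProtT5-XL-UniRef50
by default) through ``transformers``; per-residue hidden states form
the ``L x 1024`` matrix the pipeline pools.

``transformers`` and ``torch`` are deliberately not dependencies of
this package — the adapter imports them lazily and raises a clear
error when they are absent.  Everything else in the package (and the
whole test suite) runs on the deterministic mock backend instead.
"""

from __future__ import annotations

from nifcast.records import ProteinSequence
from nifcast.sequence_features import EmbeddingMatrix


class ProtT5Embedder:
    """Thin wrapper around a T5-encoder protein model."""

    width = 1024

    def __init__(self, model_name: str = "Rostlab/prot_t5_xl_half_uniref50-enc",
                 device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import T5EncoderModel, T5Tokenizer
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "the real embedding backend needs the optional 'transformers' "
                "and 'torch' packages; install them or use MockEmbedder"
            ) from exc
        self._torch = torch
        self._tokenizer = T5Tokenizer.from_pretrained(model_name)
        self._model = T5EncoderModel.from_pretrained(model_name).to(device).eval()
        self._device = device

    def embed(self, seq: ProteinSequence) -> EmbeddingMatrix:  # pragma: no cover
        torch = self._torch
        spaced = " ".join(seq.residues)
        tokens = self._tokenizer(spaced, return_tensors="pt").to(self._device)
        with torch.no_grad():
            out = self._model(**tokens).last_hidden_state[0]
        # drop the trailing special token; keep one row per residue
        mat = out[: len(seq.residues)].cpu().numpy()
        return EmbeddingMatrix(values=mat, backend_id="prot-t5-xl-uniref50")
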