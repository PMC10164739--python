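"""Training, checkpointing and sampling for the conditional sequence model.

Pre-training consumes directed (source, target, Δ) triples pooled across
activity classes; fine-tuning continues from a pre-trained checkpoint on one
class's weak→potent triples. A seeded fraction of the training triples is
held out for validation; a checkpoint is taken every epoch and the one with
minimal validation loss is returned. Sampling decodes autoregressively, by
default with multinomial sampling at temperature 1.0 (greedy decoding
available), and is deterministic under a seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..pairing import TrainingTriple
from ..tokenizer import END, START, Vocabulary
from .config import ModelConfig
from .transformer import Seq2SeqTransformer

log = logging.getLogger(__name__)


@dataclass
class Checkpoint:
    """Selected model state with its provenance."""

    epoch: int
    validation_loss: float
    parameters: list[np.ndarray]
    config: ModelConfig
    vocab_hash: str

    def build_model(self, vocab_size: int) -> Seq2SeqTransformer:
        model = Seq2SeqTransformer(vocab_size, self.config)
        model.load_state_arrays(self.parameters)
        return model

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar manifest."""
        path = Path(path)
        np.savez(path, **{f"p{i}": a for i, a in enumerate(self.parameters)})
        manifest = {
            "epoch": self.epoch,
            "validation_loss": self.validation_loss,
            "config": self.config.to_dict(),
            "vocab_hash": self.vocab_hash,
            "n_arrays": len(self.parameters),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        data = np.load(path if path.suffix == ".npz" else str(path) + ".npz"
                       if not path.exists() else path)
        arrays = [data[f"p{i}"] for i in range(manifest["n_arrays"])]
        return cls(
            epoch=manifest["epoch"],
            validation_loss=manifest["validation_loss"],
            parameters=arrays,
            config=ModelConfig.from_dict(manifest["config"]),
            vocab_hash=manifest["vocab_hash"],
        )


def encode_triples(
    triples: list[TrainingTriple], vocab: Vocabulary, max_len: int
) -> list[tuple[list[int], list[int]]]:
    """Encode triples to (source ids, target ids incl. START/END).

    The source frames SMILES + potency token; any token missing from the
    vocabulary or an unbinnable Δ raises before training starts. Sequences
    exceeding ``max_len`` are dropped with a logged count.
    """
    if not triples:
        raise ValueError("no training triples")
    encoded = []
    n_dropped = 0
    for t in triples:
        src = vocab.encode(vocab.frame_source(t.source.smiles, t.delta))
        tgt = vocab.encode(vocab.frame_target(t.target.smiles))
        if len(src) > max_len or len(tgt) > max_len:
            n_dropped += 1
            continue
        encoded.append((src, tgt))
    if n_dropped:
        log.info("dropped %d triples exceeding max_len", n_dropped)
    if not encoded:
        raise ValueError("all triples exceed max_len")
    return encoded


def _pad_batch(seqs: list[list[int]], pad: int = 0) -> np.ndarray:
    width = max(len(s) for s in seqs)
    out = np.full((len(seqs), width), pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def _batches(encoded, order, batch_size):
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        src = _pad_batch([encoded[i][0] for i in idx])
        tgt = [encoded[i][1] for i in idx]
        tgt_in = _pad_batch([s[:-1] for s in tgt])
        tgt_out = _pad_batch([s[1:] for s in tgt])
        yield src, tgt_in, tgt_out


def _run_training(
    model: Seq2SeqTransformer,
    encoded: list,
    config: ModelConfig,
    vocab_hash: str,
    epochs: int,
    checkpoint_dir: str | Path | None,
    log_path: str | Path | None,
) -> Checkpoint:
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(encoded)))) if len(encoded) > 1 else 0
    perm = rng.permutation(len(encoded))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0 or len(val_idx) == 0:
        # degenerate corpus: validate on the training instances themselves
        train_idx = val_idx = perm

    def val_loss() -> float:
        losses, weights = [], []
        for src, tin, tout in _batches(encoded, val_idx, config.batch_size):
            losses.append(model.evaluate_loss(src, tin, tout))
            weights.append(int((tout != 0).sum()))
        return float(np.average(losses, weights=weights))

    opt = model.make_optimizer()
    best = Checkpoint(
        epoch=0,
        validation_loss=val_loss(),
        parameters=[a.copy() for a in model.state_arrays()],
        config=config,
        vocab_hash=vocab_hash,
    )
    history = [(0, float("nan"), best.validation_loss)]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(train_idx)
        train_losses, train_weights = [], []
        for src, tin, tout in _batches(encoded, order, config.batch_size):
            opt.zero_grad()
            loss = model.loss_and_backward(src, tin, tout, train=True)
            opt.step()
            train_losses.append(loss)
            train_weights.append(int((tout != 0).sum()))
        vloss = val_loss()
        tloss = float(np.average(train_losses, weights=train_weights))
        history.append((epoch, tloss, vloss))
        log.info("epoch %d: train %.4f val %.4f", epoch, tloss, vloss)
        ckpt = Checkpoint(
            epoch=epoch,
            validation_loss=vloss,
            parameters=[a.copy() for a in model.state_arrays()],
            config=config,
            vocab_hash=vocab_hash,
        )
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            ckpt.save(Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz")
        if vloss < best.validation_loss:
            best = ckpt
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "validation_loss"])
            writer.writerows(history)
    best.history = history  # loss curve, kept on the returned checkpoint
    return best


def pretrain(
    triples: list[TrainingTriple],
    vocab: Vocabulary,
    config: ModelConfig,
    checkpoint_dir: str | Path | None = None,
    log_path: str | Path | None = None,
) -> Checkpoint:
    """Train the model from scratch on pooled All_CCR triples; returns the
    minimum-validation-loss checkpoint."""
    encoded = encode_triples(triples, vocab, config.max_len)
    model = Seq2SeqTransformer(len(vocab), config)
    return _run_training(model, encoded, config, vocab.digest(), config.epochs,
                         checkpoint_dir, log_path)


def finetune(
    checkpoint: Checkpoint,
    ac_triples: list[TrainingTriple],
    config: ModelConfig | None = None,
    vocab: Vocabulary | None = None,
    checkpoint_dir: str | Path | None = None,
    log_path: str | Path | None = None,
) -> Checkpoint:
    """Continue training from a pre-trained checkpoint on one activity class's
    oriented AC-CCR triples. The input checkpoint is left untouched; zero
    epochs returns a copy of the input model."""
    if vocab is None:
        raise ValueError("finetune requires the vocabulary")
    if vocab.digest() != checkpoint.vocab_hash:
        raise ValueError("vocabulary does not match the checkpoint")
    config = config or checkpoint.config
    encoded = encode_triples(ac_triples, vocab, config.max_len)
    model = Seq2SeqTransformer(len(vocab), config)
    model.load_state_arrays([a.copy() for a in checkpoint.parameters])
    return _run_training(model, encoded, config, checkpoint.vocab_hash,
                         config.epochs, checkpoint_dir, log_path)


def sample(
    checkpoint: Checkpoint,
    vocab: Vocabulary,
    source_smiles: str,
    delta: float,
    n: int = 50,
    seed: int = 0,
    greedy: bool = False,
    temperature: float = 1.0,
) -> list[str]:
    """Generate n candidate target SMILES for a (source, Δ) instance.

    Decoding is autoregressive until END or max_len; duplicates are allowed
    and validity is not checked here. Out-of-range Δ clamps to the nearest
    bin edge. Deterministic for a given (source, delta, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if vocab.digest() != checkpoint.vocab_hash:
        raise ValueError("vocabulary does not match the checkpoint")
    model = checkpoint.build_model(len(vocab))
    rng = np.random.default_rng(seed)

    src_ids = vocab.encode(vocab.frame_source(source_smiles, delta, clamp=True))
    src = np.tile(np.asarray(src_ids, dtype=np.int64), (n, 1))
    enc_out = model.encode(src, train=False)

    start_id, end_id = vocab.index(START), vocab.index(END)
    # restrict emissions to SMILES tokens + END
    forbidden = np.zeros(len(vocab), dtype=bool)
    for i, tok in enumerate(vocab.tokens):
        if vocab.is_potency_token(tok) or tok in (START,):
            forbidden[i] = True
    forbidden[model.PAD_ID] = True

    seqs = np.full((n, 1), start_id, dtype=np.int64)
    finished = np.zeros(n, dtype=bool)
    for _ in range(model.cfg.max_len - 1):
        logits = model.decode(seqs, enc_out, src, train=False)[:, -1, :]
        logits[:, forbidden] = -np.inf
        if greedy:
            nxt = logits.argmax(axis=-1)
        else:
            probs = np.exp(
                (logits - logits.max(axis=-1, keepdims=True)) / max(temperature, 1e-6))
            probs /= probs.sum(axis=-1, keepdims=True)
            cum = probs.cumsum(axis=-1)
            u = rng.random((n, 1))
            nxt = (cum < u).sum(axis=-1)
        nxt = np.where(finished, model.PAD_ID, nxt)
        seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
        finished |= nxt == end_id
        if finished.all():
            break
    out = []
    for row in seqs:
        tokens = vocab.decode(row)
        if END in tokens:
            tokens = tokens[: tokens.index(END)]
        out.append(vocab.detokenize(tokens))
    return out
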