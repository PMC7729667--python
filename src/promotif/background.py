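"""k-th-order Markov background model estimated from intergenic sequence.

The background is the null model for both motif discovery and scanning.
It is estimated on the forward strand only; strand handling during scanning
is done by reverse-complementing the query window, never the model.
Contexts never span sequence boundaries or runs of N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import SequenceSet
from .pwm import BASES, encode


@dataclass
class BackgroundModel:
    """Markov chain over {A,C,G,T} of a given order.

    ``transition`` maps each length-``order`` context string to a length-4
    probability vector; ``stationary`` is the (pseudocounted) mononucleotide
    distribution used for positions without full context.
    """

    order: int
    transition: dict[str, np.ndarray]
    stationary: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        self.stationary = np.asarray(self.stationary, dtype=float)
        if abs(self.stationary.sum() - 1.0) > 1e-9:
            raise ValueError("stationary distribution must sum to 1")
        for ctx, row in self.transition.items():
            row = np.asarray(row, dtype=float)
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"transition row for {ctx!r} must sum to 1")
            self.transition[ctx] = row

    def conditional(self, context: str) -> np.ndarray:
        """P(base | context), truncating the context to the model order.

        Shorter contexts (start of a sequence, or following an N run) fall
        back to progressively lower-order estimates ending at the stationary
        distribution.
        """
        ctx = context[-self.order :] if self.order else ""
        while True:
            if len(ctx) == 0:
                return self.stationary
            row = self.transition.get(ctx)
            if row is not None:
                return row
            ctx = ctx[1:]

    def sequence_log_prob(self, s: str) -> float:
        """log P(s) under the chain; s must be N-free and longer than order."""
        if "N" in s:
            raise ValueError("sequence contains N; pre-filter before scoring")
        if len(s) <= self.order:
            raise ValueError("sequence must be longer than the model order")
        from .pwm import BASE_INDEX

        logp = 0.0
        for i, base in enumerate(s):
            probs = self.conditional(s[max(0, i - self.order) : i])
            logp += float(np.log(probs[BASE_INDEX[base]]))
        return logp

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw one sequence of the given length from the chain."""
        out: list[str] = []
        for i in range(length):
            probs = self.conditional("".join(out[max(0, i - self.order) : i]))
            out.append(BASES[rng.choice(4, p=probs / probs.sum())])
        return "".join(out)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# order={self.order} pseudocount={float(self.pseudocount)!r}\n")
            fh.write("* " + " ".join(repr(float(v)) for v in self.stationary) + "\n")
            for ctx in sorted(self.transition):
                row = self.transition[ctx]
                fh.write(f"{ctx} " + " ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        order = 0
        pseudocount = 1.0
        stationary = None
        transition: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "order":
                            order = int(v)
                        elif k == "pseudocount":
                            pseudocount = float(v)
                    continue
                if not line:
                    continue
                key, *vals = line.split()
                vec = np.array([float(v) for v in vals])
                if key == "*":
                    stationary = vec
                else:
                    transition[key] = vec
        if stationary is None:
            raise ValueError(f"{path}: missing stationary row")
        return cls(order, transition, stationary, pseudocount)


def _segments(codes: np.ndarray) -> list[np.ndarray]:
    """Split an encoded sequence at N positions into clean segments."""
    valid = codes < 4
    segs = []
    start = None
    for i, ok in enumerate(valid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segs.append(codes[start:i])
            start = None
    if start is not None:
        segs.append(codes[start:])
    return segs


def build_background(
    intergenic: SequenceSet, order: int = 3, pseudocount: float = 1.0
) -> BackgroundModel:
    """Estimate a k-th-order Markov model from intergenic sequences.

    transition[c][b] = (count(c·b) + β) / (count(c·) + 4β); the stationary
    distribution is the pseudocounted mononucleotide frequency.  Counts are
    pooled across sequences but contexts never cross sequence boundaries.
    """
    if len(intergenic) == 0:
        raise ValueError("cannot build a background model from empty input")
    k = order
    n_contexts = 4**k
    counts = np.zeros((n_contexts, 4), dtype=float)
    mono = np.zeros(4, dtype=float)
    total_usable = 0
    powers = 4 ** np.arange(k - 1, -1, -1) if k else np.array([], dtype=int)
    for seq in intergenic.records.values():
        codes = encode(seq)
        for seg in _segments(codes):
            mono += np.bincount(seg, minlength=4)
            total_usable += len(seg)
            if len(seg) <= k:
                continue
            if k == 0:
                ctx_idx = np.zeros(len(seg), dtype=int)
                nxt = seg
            else:
                # rolling context index over the segment
                windows = np.lib.stride_tricks.sliding_window_view(seg, k)[:-1]
                ctx_idx = windows @ powers
                nxt = seg[k:]
            np.add.at(counts, (ctx_idx, nxt), 1.0)
    if total_usable == 0:
        raise ValueError("no usable (non-N) sequence in background input")
    if total_usable < 4 ** (k + 1):
        import warnings

        warnings.warn(
            f"background input has only {total_usable} usable bases; "
            f"recommend >= {4 ** (k + 1)} for order {k}",
            stacklevel=2,
        )
    stationary = (mono + pseudocount) / (mono.sum() + 4 * pseudocount)
    transition: dict[str, np.ndarray] = {}
    contexts = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    for idx, ctx in enumerate(contexts):
        row = counts[idx]
        denom = row.sum() + 4 * pseudocount
        if pseudocount == 0 and row.sum() == 0:
            continue  # unseen context with no smoothing: fall back at query time
        transition[ctx] = (row + pseudocount) / denom
    return BackgroundModel(k, transition, stationary, pseudocount)


def _dense_log_transition(model: BackgroundModel) -> np.ndarray:
    """Lazily cached ``(4^k, 4)`` log-transition array in lexicographic
    context order; unseen contexts fall back through shorter contexts."""
    cached = getattr(model, "_dense_log_transition", None)
    if cached is not None:
        return cached
    import itertools as _it

    from .pwm import BASES as _B

    k = model.order
    dense = np.empty((4**k, 4), dtype=float)
    for idx, ctx in enumerate("".join(p) for p in _it.product(_B, repeat=k)):
        dense[idx] = np.log(model.conditional(ctx))
    model._dense_log_transition = dense  # type: ignore[attr-defined]
    return dense


def contextual_log_probs(model: BackgroundModel, codes: np.ndarray) -> np.ndarray:
    """Per-position log P(base_i | preceding context) over a whole sequence.

    Returns shape ``(L, 4)``: column b at row i is log P(b | s[i-k:i]).
    Positions whose context window touches an N fall back to shorter
    contexts, matching :meth:`BackgroundModel.conditional`.  Rows at N
    positions are still filled (scanning skips N windows separately).
    """
    from .pwm import BASES as _B

    L = len(codes)
    k = model.order
    out = np.empty((L, 4), dtype=float)
    log_stat = np.log(model.stationary)
    if k == 0:
        out[:] = log_stat
        return out
    dense = _dense_log_transition(model)
    out[: min(k, L)] = _slow_rows(model, codes, range(min(k, L)))
    if L <= k:
        return out
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[: L - k]
    clean = np.all(windows < 4, axis=1)
    ctx_idx = np.minimum(windows, 3) @ powers
    out[k:] = dense[ctx_idx]
    dirty = np.nonzero(~clean)[0]
    if len(dirty):
        out[k:][dirty] = _slow_rows(model, codes, (int(d) + k for d in dirty))
    return out


def _slow_rows(model: BackgroundModel, codes: np.ndarray, positions) -> np.ndarray:
    from .pwm import BASES as _B

    rows = []
    for i in positions:
        lo = max(0, i - model.order)
        ctx_codes = codes[lo:i]
        bad = np.nonzero(ctx_codes >= 4)[0]
        if len(bad):
            ctx_codes = ctx_codes[bad[-1] + 1 :]
        ctx = "".join(_B[c] for c in ctx_codes)
        rows.append(np.log(model.conditional(ctx)))
    return np.array(rows).reshape(-1, 4)
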