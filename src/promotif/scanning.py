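"""PWM scanning of promoter sequences.

Two scanning contracts are provided:

* :func:`scan_normalized` — a locator-style scan: per-window log-odds against
  the (possibly higher-order) background, min-max normalised per window, hit
  when the normalised score reaches the threshold (default 0.9);
* :func:`scan_pvalue` — a FIMO-style scan: log-odds against the order-0
  stationary background, with exact p-values from the dynamic-programming
  null distribution over an integer-rescaled score lattice.

Both scan both strands and skip windows containing N.  Downstream helpers
compute per-motif mapping rates with the fold-enrichment rule, build
consensus sites where several TF families hit the same coordinates, and mark
genes by their TFBS load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import BackgroundModel, contextual_log_probs
from .promoters import PromoterUniverse
from .pwm import PWM, encode

LATTICE_BINS = 1000


@dataclass
class MotifHit:
    promoter_id: str
    motif_id: str
    tf_family: str
    interval: tuple[int, int]  # 0-based half-open on the promoter
    strand: str
    raw_score: float
    normalized_score: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.normalized_score is not None and not (
            -1e-9 <= self.normalized_score <= 1 + 1e-9
        ):
            raise ValueError("normalized_score must lie in [0, 1]")


@dataclass
class ConsensusSite:
    promoter_id: str
    interval: tuple[int, int]
    families: frozenset[str]
    supporting_hits: list[MotifHit]

    def __post_init__(self) -> None:
        if len(self.families) < 2:
            raise ValueError("a consensus site needs >= 2 TF families")


@dataclass
class GeneTFBSStatus:
    gene_id: str
    n_hits_per_family: dict[str, int]
    has_consensus: bool

    @property
    def total_hits(self) -> int:
        return sum(self.n_hits_per_family.values())

    @property
    def marked(self) -> bool:
        return self.total_hits > 1 or self.has_consensus


@dataclass
class MappingRateResult:
    motif_id: str
    rate_target: float
    rate_random: float
    enriched: bool
    fold: float


def _prepare(sequence: str, background: BackgroundModel):
    """Encode a promoter and precompute per-position background
    log-probability rows for both reading directions."""
    from .pwm import COMPLEMENT

    codes = encode(sequence)
    rc_codes = np.where(codes[::-1] < 4, COMPLEMENT[np.minimum(codes[::-1], 3)], 4)
    ctx_f = contextual_log_probs(background, codes)
    ctx_r = contextual_log_probs(background, rc_codes)
    return codes, rc_codes, ctx_f, ctx_r


def _window_valid(codes: np.ndarray, width: int) -> np.ndarray:
    is_n = (codes >= 4).astype(float)
    c = np.concatenate([[0.0], np.cumsum(is_n)])
    return (c[width:] - c[:-width]) == 0


def scan_normalized(
    promoters: PromoterUniverse,
    pwm: PWM,
    background: BackgroundModel,
    t: float = 0.9,
    tf_family: str = "",
) -> list[MotifHit]:
    """Locator-style scan: emit hits with min-max normalised log-odds >= t.

    For a window at position j the raw score is
    ``sum_i log(pwm[i, base] / P(base | context))`` and the normalised score
    rescales it between the per-window minimum and maximum achievable under
    the same background-conditional denominators.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold t must lie in [0, 1]")
    w = pwm.width
    logpwm = pwm.log_matrix()
    hits: list[MotifHit] = []
    for rec in promoters.records:
        L = len(rec.sequence)
        if L <= w:
            continue
        codes, rc_codes, ctx_f, ctx_r = _prepare(rec.sequence, background)
        for view, vcodes, ctx in ((0, codes, ctx_f), (1, rc_codes, ctx_r)):
            n = L - w + 1
            valid = _window_valid(vcodes, w)
            # per-position log-odds rows for this window frame
            raw = np.zeros(n)
            lo = np.zeros(n)
            hi = np.zeros(n)
            for i in range(w):
                odds = logpwm[i][None, :] - ctx[i : i + n]  # (n, 4)
                safe = np.minimum(vcodes[i : i + n], 3)
                raw += odds[np.arange(n), safe]
                lo += odds.min(axis=1)
                hi += odds.max(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                span = hi - lo
                norm = np.where(span > 0, (raw - lo) / span, 1.0)
            for j in np.nonzero(valid & (norm >= t))[0]:
                if view == 0:
                    start = int(j)
                    strand = "+"
                else:
                    start = L - w - int(j)
                    strand = "-"
                hits.append(
                    MotifHit(
                        promoter_id=rec.transcript_id,
                        motif_id=pwm.motif_id,
                        tf_family=tf_family,
                        interval=(start, start + w),
                        strand=strand,
                        raw_score=float(raw[j]),
                        normalized_score=float(min(max(norm[j], 0.0), 1.0)),
                    )
                )
    hits.sort(key=lambda h: (h.promoter_id, h.interval, h.strand))
    return hits


def pvalue_lattice(pwm: PWM, stationary: np.ndarray):
    """Integer-rescaled log-odds matrix and the exact null survival function.

    The log-odds matrix against the order-0 stationary background is mapped
    onto a ``LATTICE_BINS``-step integer lattice; the null distribution of
    the integer score under the background is computed by exact dynamic
    programming (convolution over positions).
    """
    w = pwm.width
    logodds = pwm.log_matrix() - np.log(stationary)[None, :]
    lo, hi = logodds.min(), logodds.max()
    scale = LATTICE_BINS / (hi - lo) if hi > lo else 1.0
    q = np.rint((logodds - lo) * scale).astype(int)  # (w, 4), values in [0, BINS]
    max_total = int(q.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    for i in range(w):
        step = np.zeros(int(q[i].max()) + 1)
        for b in range(4):
            step[q[i, b]] += stationary[b]
        pmf = np.convolve(pmf, step)
    sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])  # sf[s] = P(S >= s)
    np.minimum(sf, 1.0, out=sf)  # guard against fp accumulation above 1
    return q, sf


def scan_pvalue(
    promoters: PromoterUniverse,
    pwm: PWM,
    background: BackgroundModel,
    p_threshold: float = 1e-4,
    tf_family: str = "",
) -> list[MotifHit]:
    """FIMO-style scan: exact p-values under the order-0 stationary null."""
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    w = pwm.width
    stationary = background.stationary
    q, sf = pvalue_lattice(pwm, stationary)
    q5 = np.zeros((w, 5), dtype=int)
    q5[:, :4] = q
    log_stat = np.log(stationary)
    logpwm = pwm.log_matrix()
    hits: list[MotifHit] = []
    for rec in promoters.records:
        L = len(rec.sequence)
        if L <= w:
            continue
        codes = encode(rec.sequence)
        from .pwm import COMPLEMENT

        rc_codes = np.where(codes[::-1] < 4, COMPLEMENT[np.minimum(codes[::-1], 3)], 4)
        for view, vcodes in ((0, codes), (1, rc_codes)):
            n = L - w + 1
            valid = _window_valid(vcodes, w)
            iscore = np.zeros(n, dtype=int)
            raw = np.zeros(n)
            for i in range(w):
                col = vcodes[i : i + n]
                iscore += q5[i][col]
                safe = np.minimum(col, 3)
                raw += logpwm[i][safe] - log_stat[safe]
            pvals = sf[np.minimum(iscore, len(sf) - 1)]
            for j in np.nonzero(valid & (pvals <= p_threshold))[0]:
                if view == 0:
                    start, strand = int(j), "+"
                else:
                    start, strand = L - w - int(j), "-"
                hits.append(
                    MotifHit(
                        promoter_id=rec.transcript_id,
                        motif_id=pwm.motif_id,
                        tf_family=tf_family,
                        interval=(start, start + w),
                        strand=strand,
                        raw_score=float(raw[j]),
                        p_value=float(min(pvals[j], 1.0)) or np.nextafter(0, 1),
                    )
                )
    hits.sort(key=lambda h: (h.promoter_id, h.interval, h.strand))
    return hits


def mapping_rate(
    hits: list[MotifHit],
    target_universe: PromoterUniverse,
    random_universe: PromoterUniverse,
    random_hits: list[MotifHit],
    fold: float = 1.5,
    rule: str = "fold",
) -> MappingRateResult:
    """Per-motif mapping rates on target vs random promoters.

    ``rule='fold'`` (default) calls the motif enriched when the target rate
    exceeds ``fold`` times the random rate, i.e. exceeds it by more than
    50% at the default fold of 1.5.  ``rule='absolute'`` is the literal
    alternative reading: target rate > 0.5 * random rate.
    """
    if len(target_universe) == 0 or len(random_universe) == 0:
        raise ValueError("mapping rate needs non-empty universes")
    target_ids = set(target_universe.ids())
    random_ids = set(random_universe.ids())
    hit_t = {h.promoter_id for h in hits} & target_ids
    hit_r = {h.promoter_id for h in random_hits} & random_ids
    rate_t = len(hit_t) / len(target_ids)
    rate_r = len(hit_r) / len(random_ids)
    if rule == "fold":
        enriched = rate_t > fold * rate_r
    elif rule == "absolute":
        enriched = rate_t > 0.5 * rate_r
    else:
        raise ValueError(f"unknown mapping-rate rule {rule!r}")
    motif_id = hits[0].motif_id if hits else (random_hits[0].motif_id if random_hits else "")
    return MappingRateResult(motif_id, rate_t, rate_r, enriched, fold)


def build_consensus(
    hits: list[MotifHit], colocate: str = "identical"
) -> list[ConsensusSite]:
    """Group co-located hits of >= 2 distinct TF families into consensus sites.

    ``identical`` mode requires exactly shared intervals; ``overlap`` mode
    takes connected components of the >= 1 bp-overlap graph per promoter and
    reports the union interval.  Output is deterministic under input
    permutation.
    """
    out: list[ConsensusSite] = []
    by_prom: dict[str, list[MotifHit]] = {}
    for h in sorted(hits, key=lambda h: (h.promoter_id, h.interval, h.motif_id, h.strand)):
        by_prom.setdefault(h.promoter_id, []).append(h)
    for prom, phits in sorted(by_prom.items()):
        if colocate == "identical":
            by_iv: dict[tuple[int, int], list[MotifHit]] = {}
            for h in phits:
                by_iv.setdefault(h.interval, []).append(h)
            for iv, group in sorted(by_iv.items()):
                fams = frozenset(h.tf_family for h in group)
                if len(fams) >= 2:
                    out.append(ConsensusSite(prom, iv, fams, group))
        elif colocate == "overlap":
            # connected components of the pairwise-overlap graph via sweep
            comps: list[list[MotifHit]] = []
            cur: list[MotifHit] = []
            cur_end = -1
            for h in sorted(phits, key=lambda h: h.interval):
                if cur and h.interval[0] < cur_end:
                    cur.append(h)
                    cur_end = max(cur_end, h.interval[1])
                else:
                    if cur:
                        comps.append(cur)
                    cur = [h]
                    cur_end = h.interval[1]
            if cur:
                comps.append(cur)
            for group in comps:
                fams = frozenset(h.tf_family for h in group)
                if len(fams) >= 2:
                    iv = (
                        min(h.interval[0] for h in group),
                        max(h.interval[1] for h in group),
                    )
                    out.append(ConsensusSite(prom, iv, fams, group))
        else:
            raise ValueError(f"unknown colocate mode {colocate!r}")
    return out


def mark_genes(
    hits: list[MotifHit],
    consensus: list[ConsensusSite],
    promoter_to_gene: dict[str, str],
) -> list[GeneTFBSStatus]:
    """Tally per-family hits per gene and mark genes with more than one
    binding event or a consensus site in the promoter."""
    for h in hits:
        if h.promoter_id not in promoter_to_gene:
            raise KeyError(f"hit references unknown promoter {h.promoter_id!r}")
    genes: dict[str, dict[str, int]] = {}
    for gene in promoter_to_gene.values():
        genes.setdefault(gene, {})
    for h in hits:
        fam = h.tf_family or h.motif_id
        tally = genes[promoter_to_gene[h.promoter_id]]
        tally[fam] = tally.get(fam, 0) + 1
    consensus_genes = {
        promoter_to_gene[c.promoter_id]
        for c in consensus
        if c.promoter_id in promoter_to_gene
    }
    return [
        GeneTFBSStatus(gene, tally, gene in consensus_genes)
        for gene, tally in sorted(genes.items())
    ]
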