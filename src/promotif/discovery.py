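"""De novo motif discovery by Gibbs site sampling.

The sampler is the classic one-site-per-sequence scheme: hold one sequence
out, estimate a PWM from the remaining sites (with background-proportional
pseudocounts), score every window of the held-out sequence on both strands
by the log-likelihood ratio against the Markov background, and resample the
held-out site from the exponentiated ratios.  Discovery is replicated over
many independently seeded runs; motifs recurring in enough runs are "valid".

After the sampling phase the best-scoring visited state is kept, up to
``max_sites_per_seq - 1`` extra occurrences per sequence are added above the
weakest sampled site's score, accepted sites are masked with N, and the
sampler repeats for the next motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .background import BackgroundModel, contextual_log_probs
from .comparison import kl_distance
from .promoters import PromoterUniverse
from .pwm import PWM, encode

logger = logging.getLogger(__name__)

NEG_INF = -np.inf


@dataclass
class Site:
    promoter_id: str
    offset: int  # 0-based on the promoter, forward coordinates
    strand: str


@dataclass
class MotifCandidate:
    pwm: PWM
    run_id: int
    score: float
    sites: list[Site]
    information_content: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("candidate score must be finite")
        if not self.sites:
            raise ValueError("candidate must have at least one site")

    @property
    def width(self) -> int:
        return self.pwm.width

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class MotifGroup:
    group_id: str
    representative: PWM
    members: list[MotifCandidate]
    rep_weight: float = 0.0
    valid: bool = False

    @property
    def n_runs_found(self) -> int:
        return len({m.run_id for m in self.members})

    @property
    def score(self) -> float:
        return max(m.score for m in self.members)


class _SeqView:
    """Forward and reverse-complement encoded views of one promoter with
    per-position background log-probabilities, rebuilt after masking.

    Per-width window background sums and validity masks are cached and
    invalidated on masking, since they dominate the sampler's inner loop."""

    def __init__(self, promoter_id: str, sequence: str, background: BackgroundModel):
        self.promoter_id = promoter_id
        self.background = background
        self.codes = encode(sequence)
        self.length = len(self.codes)
        self._rebuild()

    def _rebuild(self) -> None:
        from .pwm import COMPLEMENT

        self.rc_codes = np.where(
            self.codes[::-1] < 4, COMPLEMENT[np.minimum(self.codes[::-1], 3)], 4
        )
        self.bg_base_logp = [
            self._base_logp(self.codes),
            self._base_logp(self.rc_codes),
        ]
        self._bg_cache: dict[tuple[int, int], np.ndarray] = {}
        self._valid_cache: dict[tuple[int, int], np.ndarray] = {}

    def _base_logp(self, codes: np.ndarray) -> np.ndarray:
        ctx = contextual_log_probs(self.background, codes)
        out = np.zeros(len(codes))
        valid = codes < 4
        out[valid] = ctx[valid, codes[valid]]
        return out

    def mask(self, offset: int, width: int) -> None:
        """Replace a forward-coordinate window with N and rebuild."""
        self.codes[offset : offset + width] = 4
        self._rebuild()

    def window_bg_logp(self, view: int, width: int) -> np.ndarray:
        key = (view, width)
        if key not in self._bg_cache:
            base = self.bg_base_logp[view]
            c = np.concatenate([[0.0], np.cumsum(base)])
            self._bg_cache[key] = c[width:] - c[:-width]
        return self._bg_cache[key]

    def valid_windows(self, view: int, width: int) -> np.ndarray:
        key = (view, width)
        if key not in self._valid_cache:
            codes = self.codes if view == 0 else self.rc_codes
            is_n = (codes >= 4).astype(float)
            c = np.concatenate([[0.0], np.cumsum(is_n)])
            self._valid_cache[key] = (c[width:] - c[:-width]) == 0
        return self._valid_cache[key]

    def view_codes(self, view: int) -> np.ndarray:
        return self.codes if view == 0 else self.rc_codes

    def to_forward(self, view: int, offset: int, width: int) -> tuple[int, str]:
        if view == 0:
            return offset, "+"
        return self.length - width - offset, "-"


def _window_scores(logpwm5: np.ndarray, codes: np.ndarray, width: int) -> np.ndarray:
    """Sum of per-column log-probabilities over every window; N gives -inf."""
    n = len(codes) - width + 1
    if n <= 0:
        return np.empty(0)
    s = logpwm5[0][codes[:n]].copy()
    for t in range(1, width):
        s += logpwm5[t][codes[t : t + n]]
    return s


def _extend_logpwm(log_matrix: np.ndarray) -> np.ndarray:
    """Append a -inf column for the N code so masked windows score -inf."""
    w = log_matrix.shape[0]
    out = np.full((w, 5), NEG_INF)
    out[:, :4] = log_matrix
    return out


def _ratio_scores(view: "_SeqView", v: int, logpwm5: np.ndarray, width: int) -> np.ndarray:
    scores = _window_scores(logpwm5, view.view_codes(v), width)
    bg = view.window_bg_logp(v, width)
    with np.errstate(invalid="ignore"):
        out = scores - bg
    out[~view.valid_windows(v, width)] = NEG_INF
    return out


def _pwm_from_sites(
    site_windows: list[np.ndarray], width: int, pseudo: np.ndarray
) -> np.ndarray:
    counts = np.zeros((width, 4))
    for win in site_windows:
        counts[np.arange(width), win] += 1.0
    counts += pseudo
    return counts / counts.sum(axis=1, keepdims=True)


def _sample_one_motif(
    views: list[_SeqView],
    width: int,
    background: BackgroundModel,
    rng: np.random.Generator,
    n_iterations: int,
    max_sites_per_seq: int,
    gamma: float,
) -> tuple[PWM, float, list[Site], list[tuple[int, int, int]]] | None:
    """One round of the site sampler at a fixed width.

    Returns (pwm, score, sites, site_coords) or None when fewer than two
    sequences still contain a scoreable window.
    """
    pseudo = gamma * background.stationary
    active: list[int] = []
    state: dict[int, tuple[int, int]] = {}  # seq index -> (view, offset)
    for i, view in enumerate(views):
        choices = [
            (v, off)
            for v in (0, 1)
            for off in np.nonzero(view.valid_windows(v, width))[0]
        ]
        if choices:
            active.append(i)
            state[i] = choices[rng.integers(len(choices))]
    if len(active) < 2:
        return None

    def site_window(i: int) -> np.ndarray:
        v, off = state[i]
        return views[i].view_codes(v)[off : off + width]

    def site_ratio(i: int, logpwm5: np.ndarray) -> float:
        v, off = state[i]
        win = site_window(i)
        return float(
            logpwm5[np.arange(width), win].sum()
            - views[i].window_bg_logp(v, width)[off]
        )

    arange_w = np.arange(width)
    # running counts over all current sites, updated incrementally
    counts = pseudo[None, :].repeat(width, axis=0).astype(float)
    for i in active:
        counts[arange_w, site_window(i)] += 1.0

    best_state: dict[int, tuple[int, int]] | None = None
    best_total = NEG_INF
    for _sweep in range(n_iterations):
        for i in active:
            counts[arange_w, site_window(i)] -= 1.0
            pwm_mat = counts / counts.sum(axis=1, keepdims=True)
            logpwm5 = _extend_logpwm(np.log(pwm_mat))
            ratios = [
                _ratio_scores(views[i], v, logpwm5, width) for v in (0, 1)
            ]
            flat = np.concatenate(ratios)
            finite = np.isfinite(flat)
            if not finite.any():
                counts[arange_w, site_window(i)] += 1.0
                continue
            z = np.where(finite, flat - flat[finite].max(), NEG_INF)
            probs = np.exp(z)
            cdf = np.cumsum(probs)
            pick = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
            pick = min(pick, len(flat) - 1)
            n0 = len(ratios[0])
            state[i] = (0, pick) if pick < n0 else (1, pick - n0)
            counts[arange_w, site_window(i)] += 1.0
        # total log-ratio of the current state under its own PWM
        pwm_mat = counts / counts.sum(axis=1, keepdims=True)
        logpwm5 = _extend_logpwm(np.log(pwm_mat))
        total = sum(site_ratio(j, logpwm5) for j in active)
        if total > best_total:
            best_total = total
            best_state = dict(state)

    if best_state is None:
        return None
    state = best_state

    # final PWM and per-site ratios from the best visited state
    all_windows = [site_window(j) for j in active]
    pwm_mat = _pwm_from_sites(all_windows, width, pseudo)
    logpwm5 = _extend_logpwm(np.log(pwm_mat))
    site_ratios = {}
    ratio_cache = {}
    for j in active:
        ratio_cache[j] = [
            _ratio_scores(views[j], v, logpwm5, width) for v in (0, 1)
        ]
        v, off = state[j]
        site_ratios[j] = float(ratio_cache[j][v][off])
    tau_add = min(site_ratios.values())

    sites: list[Site] = []
    site_coords: list[tuple[int, int, int]] = []  # (seq index, fwd offset, width)
    total_score = 0.0
    for j in active:
        v0, off0 = state[j]
        accepted = [(v0, off0, site_ratios[j])]
        fwd0, _ = views[j].to_forward(v0, off0, width)
        occupied = [(fwd0, fwd0 + width)]
        # extra occurrences above the weakest sampled site, non-overlapping
        extras = []
        for v in (0, 1):
            r = ratio_cache[j][v]
            for off in np.nonzero(r > tau_add)[0]:
                extras.append((float(r[off]), v, int(off)))
        extras.sort(reverse=True)
        for score, v, off in extras:
            if len(accepted) >= max_sites_per_seq:
                break
            fwd, _ = views[j].to_forward(v, off, width)
            if any(fwd < e and fwd + width > s for s, e in occupied):
                continue
            accepted.append((v, off, score))
            occupied.append((fwd, fwd + width))
        for v, off, score in accepted:
            fwd, strand = views[j].to_forward(v, off, width)
            sites.append(Site(views[j].promoter_id, fwd, strand))
            site_coords.append((j, fwd, width))
            total_score += score

    return PWM(pwm_mat), total_score, sites, site_coords


def gibbs_discover(
    promoters: PromoterUniverse,
    background: BackgroundModel,
    widths: tuple[int, ...] = (6, 8, 10, 12),
    n_motifs_per_run: int = 6,
    max_sites_per_seq: int = 3,
    n_iterations: int = 200,
    seed: int | np.random.Generator = 0,
    gamma: float = 1.0,
    run_id: int = 0,
) -> list[MotifCandidate]:
    """One discovery run: the site sampler at each width, with masking
    between successive motifs of the same width."""
    if len(promoters) < 5:
        raise ValueError("motif discovery needs at least 5 promoters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates: list[MotifCandidate] = []
    for width in widths:
        usable = [r for r in promoters.records if r.length > width]
        if len(usable) < 2:
            continue
        views = [_SeqView(r.transcript_id, r.sequence, background) for r in usable]
        if all(np.all(v.codes >= 4) for v in views):
            raise ValueError("all promoters are entirely N")
        for _round in range(n_motifs_per_run):
            result = _sample_one_motif(
                views, width, background, rng, n_iterations, max_sites_per_seq, gamma
            )
            if result is None:
                break
            pwm, score, sites, site_coords = result
            candidates.append(
                MotifCandidate(
                    pwm=pwm,
                    run_id=run_id,
                    score=score,
                    sites=sites,
                    information_content=pwm.information_content(),
                )
            )
            for j, fwd, w in site_coords:
                views[j].mask(fwd, w)
    return candidates


def replicate_runs(
    promoters: PromoterUniverse,
    background: BackgroundModel,
    n_runs: int = 100,
    seed: int = 0,
    **kwargs,
) -> list[MotifCandidate]:
    """Replicate discovery over independently seeded runs.

    Per-run generators are spawned from the master seed, so the output is
    fully reproducible and runs differ only by their derived seeds.
    """
    candidates: list[MotifCandidate] = []
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for run_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        candidates.extend(
            gibbs_discover(
                promoters, background, seed=rng, run_id=run_id, **kwargs
            )
        )
    return candidates


def rank_and_group(
    candidates: list[MotifCandidate],
    distance_threshold: float = 0.3,
    min_overlap: int = 4,
) -> list[MotifGroup]:
    """Sort candidates by score and greedily agglomerate by PWM similarity.

    Each candidate joins the first existing group whose representative lies
    within the KL distance threshold over the best ungapped offset, else it
    founds a new group.  The representative is the site-count-weighted
    column average of members after offset alignment (width fixed by the
    founder).
    """
    if not candidates:
        raise ValueError("no candidates to group")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].score, candidates[i].run_id, i),
    )
    groups: list[MotifGroup] = []
    for idx in order:
        cand = candidates[idx]
        placed = False
        for group in groups:
            mo = min(min_overlap, group.representative.width, cand.pwm.width)
            match = kl_distance(group.representative, cand.pwm, min_overlap=mo)
            if match.distance <= distance_threshold:
                _merge_into(group, cand, match)
                placed = True
                break
        if not placed:
            rep = PWM(cand.pwm.matrix.copy(), motif_id=f"group_{len(groups)}")
            groups.append(
                MotifGroup(
                    group_id=f"group_{len(groups)}",
                    representative=rep,
                    members=[cand],
                    rep_weight=float(cand.n_sites),
                )
            )
    return groups


def _merge_into(group: MotifGroup, cand: MotifCandidate, match) -> None:
    """Fold a candidate's PWM into the group representative over the
    aligned overlap, weighting columns by site counts."""
    rep = group.representative
    cand_mat = (
        cand.pwm.matrix
        if match.orientation == "forward"
        else cand.pwm.reverse_complement().matrix
    )
    offset = match.offset
    a_lo = max(0, offset)
    a_hi = min(rep.width, offset + cand_mat.shape[0])
    b_lo = a_lo - offset
    m = a_hi - a_lo
    w_old, w_new = group.rep_weight, float(cand.n_sites)
    new_mat = rep.matrix.copy()
    new_mat[a_lo:a_hi] = (
        w_old * rep.matrix[a_lo:a_hi] + w_new * cand_mat[b_lo : b_lo + m]
    ) / (w_old + w_new)
    group.representative = PWM(new_mat, motif_id=rep.motif_id)
    group.rep_weight = w_old + w_new
    group.members.append(cand)


def filter_valid(
    groups: list[MotifGroup], min_runs: int = 10, total_runs: int = 100
) -> list[MotifGroup]:
    """Keep groups recovered in at least ``min_runs`` distinct runs."""
    if min_runs > total_runs:
        raise ValueError("min_runs cannot exceed total_runs")
    out = []
    for g in groups:
        g.valid = g.n_runs_found >= min_runs
        if g.valid:
            out.append(g)
    return out


def dedupe_across_widths(
    groups_by_width: dict[int, list[MotifGroup]] | list[MotifGroup],
    distance_threshold: float = 0.3,
    min_overlap: int = 4,
) -> list[MotifGroup]:
    """Merge redundant groups across widths (self-mapping of the valid set).

    The shorter motif is slid along the longer; pairs within the KL
    threshold are merged keeping the representative with the higher run
    count.  The operation is idempotent.
    """
    if isinstance(groups_by_width, dict):
        pooled = [g for groups in groups_by_width.values() for g in groups]
    else:
        pooled = list(groups_by_width)
    pooled = sorted(
        pooled, key=lambda g: (-g.n_runs_found, -g.representative.width, g.group_id)
    )
    kept: list[MotifGroup] = []
    for g in pooled:
        merged = False
        for h in kept:
            mo = min(min_overlap, g.representative.width, h.representative.width)
            match = kl_distance(h.representative, g.representative, min_overlap=mo)
            if match.distance <= distance_threshold:
                h.members.extend(g.members)
                merged = True
                break
        if not merged:
            kept.append(g)
    return kept


def write_groups_tsv(groups: list[MotifGroup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\twidth\tn_runs_found\tscore\tinformation_content\n")
        for g in groups:
            fh.write(
                f"{g.group_id}\t{g.representative.width}\t{g.n_runs_found}\t"
                f"{g.score:.6g}\t{g.representative.information_content():.4f}\n"
            )
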