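"""Diploid genotype imputation and phasing against a phased panel.

The model is the Li–Stephens haplotype-copying HMM in its diploid form:
the hidden state at each panel site is an ordered pair of panel
haplotypes being copied, transitions apply an independent per-haplotype
switch probability p = 1 - exp(-4·Ne·d/K) for genetic distance d
(Morgans) and K retained haplotypes, with switches landing uniformly,
and emissions mix the copied alleles with a mutation parameter theta
before weighting by the site's read-evidence genotype likelihoods.
Sites without read evidence take flat emissions, so their calls come
entirely from the panel mosaic — that is the imputation.

Forward–backward runs with per-site scaling on the K x K joint state
matrix; the per-haplotype transition operator factorises as
F' = A F Aᵀ with A = (1-p)·I + (p/K)·J, so each update is O(K²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import GeneticMap, PhasedCallset, ReferencePanel
from .genotype import GenotypeLikelihoodTrack

__all__ = [
    "ImputationParams",
    "impute_diploid",
    "select_states",
    "ligate_chunks",
    "diploid_posteriors",
    "watterson_theta",
]


@dataclass(frozen=True)
class ImputationParams:
    """Tunable parameters of the copying model.

    n_eff scales recombination intensity (default 10,000, human-like);
    theta is the haplotype-copying mismatch probability (default: the
    Watterson-style estimate, see ``watterson_theta``); k_states caps
    the per-chunk panel subset; chunk_len is the bp span processed per
    chunk before ligation.
    """

    n_eff: float = 10_000.0
    theta: float | None = None
    k_states: int = 32
    chunk_len: int = 20_000_000
    chunk_overlap: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta is not None and not 0.0 < self.theta < 0.5:
            raise ValueError("theta must be in (0, 0.5)")
        if self.k_states < 2:
            raise ValueError("k_states must be >= 2")


def watterson_theta(n_hap: int) -> float:
    """Copying mismatch rate from the Watterson estimator.

    theta_w = 1/sum_{i<n} 1/i, scaled to a per-site mismatch probability
    theta_w / (2 (theta_w + n)) as in Li & Stephens; floored at 1e-4.
    """
    if n_hap < 2:
        return 1e-3
    tw = 1.0 / np.sum(1.0 / np.arange(1, n_hap))
    return max(tw / (2.0 * (tw + n_hap)), 1e-4)


def _switch_probs(
    positions: np.ndarray, gmap: GeneticMap, n_eff: float, k: int
) -> np.ndarray:
    """Per-interval single-haplotype switch probability."""
    cm = np.asarray(gmap.interpolate_cM(positions), dtype=np.float64)
    d_morgans = np.maximum(np.diff(cm), 0.0) / 100.0
    rho = 4.0 * n_eff * d_morgans / k
    return 1.0 - np.exp(-rho)


def _emissions(alt: np.ndarray, gl_linear: np.ndarray, theta: float) -> np.ndarray:
    """Per-site K x K emission probabilities.

    alt: (K, S) panel alleles; gl_linear: (S, 3) linear-scale genotype
    likelihoods (flat rows for sites without evidence).
    Returns (S, K, K).
    """
    p = alt * (1 - theta) + (1 - alt) * theta  # (K, S) P(copied allele is ALT)
    q = 1.0 - p
    l0, l1, l2 = gl_linear[:, 0], gl_linear[:, 1], gl_linear[:, 2]
    # outer products per site: e = q1 q2 L0 + (p1 q2 + q1 p2) L1 + p1 p2 L2
    e = (
        np.einsum("ks,ms->skm", q, q) * l0[:, None, None]
        + (np.einsum("ks,ms->skm", p, q) + np.einsum("ks,ms->skm", q, p))
        * l1[:, None, None]
        + np.einsum("ks,ms->skm", p, p) * l2[:, None, None]
    )
    return e


def _transition_apply(F: np.ndarray, p: float, k: int) -> np.ndarray:
    """(A F Aᵀ) for A = (1-p) I + (p/k) J; A is symmetric."""
    q = p / k
    G = (1.0 - p) * F + q * F.sum(axis=0, keepdims=True)
    return (1.0 - p) * G + q * G.sum(axis=1, keepdims=True)


def diploid_posteriors(
    alt: np.ndarray,
    gl_linear: np.ndarray,
    switch: np.ndarray,
    theta: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward–backward over the ordered-pair state space.

    Returns (posteriors (S, K, K), emissions (S, K, K), log-likelihood).
    Posterior matrices each sum to 1.
    """
    K, S = alt.shape
    E = _emissions(alt, gl_linear, theta)
    fwd = np.empty((S, K, K))
    scale = np.empty(S)
    f = E[0] / (K * K)
    scale[0] = f.sum()
    fwd[0] = f / scale[0]
    for s in range(1, S):
        f = _transition_apply(fwd[s - 1], switch[s - 1], K) * E[s]
        scale[s] = f.sum()
        fwd[s] = f / scale[s]
    post = np.empty((S, K, K))
    b = np.ones((K, K))
    post[S - 1] = fwd[S - 1]
    for s in range(S - 2, -1, -1):
        b = _transition_apply(E[s + 1] * b, switch[s], K)
        b /= b.max()  # prevent underflow; posterior is renormalised below
        pm = fwd[s] * b
        post[s] = pm / pm.sum()
    loglik = float(np.log(scale).sum())
    return post, E, loglik


def select_states(
    panel: ReferencePanel, track: GenotypeLikelihoodTrack | None, k: int
) -> np.ndarray:
    """Indices of the k panel haplotypes most consistent with the rough calls.

    Agreement is measured against posterior-mean ALT dosage at sites with
    read evidence; ties resolve to the lower original haplotype index.
    With k >= panel size (or no evidence), the full panel is returned.
    """
    n = panel.n_haplotypes
    if k >= n or track is None or track.n_sites == 0:
        return np.arange(n)
    key_to_col = {s.key(): j for j, s in enumerate(panel.sites)}
    cols, dosages = [], []
    post = track.posteriors()
    for i, site in enumerate(track.sites):
        j = key_to_col.get(site.key())
        if j is None or track.depth[i] == 0:
            continue
        cols.append(j)
        dosages.append(post[i, 1] + 2.0 * post[i, 2])
    if not cols:
        return np.arange(n)
    sub = panel.haplotypes[:, cols].astype(np.float64)  # (n, m)
    d = np.asarray(dosages) / 2.0  # expected per-haplotype allele
    scores = -np.abs(sub - d[None, :]).sum(axis=1)
    order = np.argsort(-scores, kind="stable")  # stable => ties by index
    return np.sort(order[:k])


def impute_diploid(
    track: GenotypeLikelihoodTrack | None,
    panel: ReferencePanel,
    gmap: GeneticMap,
    params: ImputationParams = ImputationParams(),
) -> PhasedCallset:
    """Phased genotype calls at every panel site.

    The call at each site is the argmax of the marginal allele-pair
    posterior (ties prefer more REF alleles, then 0|1 over 1|0);
    heterozygous calls are oriented by the maximum-posterior ordered
    state at the site, which keeps phase consistent between sites
    because the copied pair changes slowly along the genome.
    """
    if panel.n_sites == 0 or panel.n_haplotypes == 0:
        raise ValueError("empty reference panel")
    key_to_col = {s.key(): j for j, s in enumerate(panel.sites)}
    if track is not None:
        for site in track.sites:
            if site.key() not in key_to_col:
                raise ValueError(
                    f"track site {site.contig}:{site.pos + 1} {site.ref}>{site.alt} "
                    "is not a panel site"
                )
    positions = panel.positions
    span = positions[-1] - positions[0] if panel.n_sites > 1 else 0
    if span <= params.chunk_len:
        return _impute_chunk(track, panel, gmap, params, np.arange(panel.n_sites))
    # chunk by bp with overlap, then ligate
    edges = np.arange(positions[0], positions[-1] + params.chunk_len, params.chunk_len)
    chunks = []
    for lo in edges[:-1]:
        hi = lo + params.chunk_len
        mask = (positions >= lo - params.chunk_overlap) & (
            positions < hi + params.chunk_overlap
        )
        idx = np.flatnonzero(mask)
        if idx.size:
            chunks.append(_impute_chunk(track, panel, gmap, params, idx))
    return ligate_chunks(chunks)


def _impute_chunk(
    track, panel, gmap, params, site_idx: np.ndarray
) -> PhasedCallset:
    sites = [panel.sites[i] for i in site_idx]
    sub_keys = {s.key(): j for j, s in enumerate(sites)}
    S = len(sites)
    gl_linear = np.ones((S, 3)) / 3.0
    depth = np.zeros(S, dtype=np.int64)
    sub_track = None
    if track is not None:
        rows = [
            (sub_keys[s.key()], i)
            for i, s in enumerate(track.sites)
            if s.key() in sub_keys
        ]
        for j, i in rows:
            lin = 10.0 ** track.gl[i]
            gl_linear[j] = lin / lin.sum()
            depth[j] = track.depth[i]
        keep = [i for _, i in rows]
        sub_track = track.subset(np.isin(np.arange(track.n_sites), keep))
    hap_idx = select_states(
        _panel_slice(panel, site_idx), sub_track, params.k_states
    )
    alt = panel.haplotypes[np.ix_(hap_idx, site_idx)].astype(np.float64)
    K = alt.shape[0]
    theta = params.theta if params.theta is not None else watterson_theta(K)
    positions = np.array([s.pos for s in sites])
    switch = _switch_probs(positions, gmap, params.n_eff, K)
    post, E, _ = diploid_posteriors(alt, gl_linear, switch, theta)

    p_alt = alt * (1 - theta) + (1 - alt) * theta  # (K, S)
    genotypes = np.zeros((S, 2), dtype=np.uint8)
    gp = np.zeros(S)
    prev_pair: tuple[int, int] | None = None
    for s in range(S):
        W = post[s] / E[s]
        v1 = p_alt[:, s]
        v0 = 1.0 - v1
        lin = gl_linear[s]
        pr = np.array(
            [
                lin[0] * (v0 @ W @ v0),
                lin[1] * (v0 @ W @ v1),
                lin[1] * (v1 @ W @ v0),
                lin[2] * (v1 @ W @ v1),
            ]
        )
        pr /= pr.sum()
        # genotype posterior aggregates the two orderings of the HET;
        # the argmax order (0/0, HET, 1/1) encodes the tie rule
        pg = np.array([pr[0], pr[1] + pr[2], pr[3]])
        call = int(np.argmax(pg))
        # stitch phase through the maximum-posterior ordered state; the
        # unordered MAP pair is oriented to keep any shared copied
        # haplotype in the same slot as at the previous site (ties ->
        # lower haplotype-index pair)
        j1, j2 = np.unravel_index(int(np.argmax(post[s])), post[s].shape)
        lo_, hi_ = (int(j1), int(j2)) if j1 <= j2 else (int(j2), int(j1))
        pair = (lo_, hi_)
        if prev_pair is not None and lo_ != hi_:
            keep = (lo_ == prev_pair[0]) + (hi_ == prev_pair[1])
            swap = (hi_ == prev_pair[0]) + (lo_ == prev_pair[1])
            if swap > keep:
                pair = (hi_, lo_)
        prev_pair = pair
        if call == 1:
            a_map = (int(round(alt[pair[0], s])), int(round(alt[pair[1], s])))
            genotypes[s] = (1, 0) if a_map == (1, 0) else (0, 1)
        else:
            genotypes[s] = (0, 0) if call == 0 else (1, 1)
        gp[s] = pg[call]
    return PhasedCallset(
        sites,
        genotypes,
        posterior=gp,
        imputed=depth == 0,
        phased=True,
    )


def _panel_slice(panel: ReferencePanel, site_idx: np.ndarray) -> ReferencePanel:
    return ReferencePanel(
        [panel.sites[i] for i in site_idx],
        panel.haplotypes[:, site_idx],
        samples=panel.samples,
    )


def ligate_chunks(chunks: list[PhasedCallset]) -> PhasedCallset:
    """Stitch overlapping chunk callsets into one genome-wide callset.

    Adjacent chunks' haplotype labels are aligned by majority vote over
    heterozygous calls in the overlap; with no overlapping HETs the
    chunks are concatenated as-is (a phase break, warned about).
    """
    import warnings as _w

    if not chunks:
        raise ValueError("no chunks to ligate")
    if len(chunks) == 1:
        return chunks[0]
    first = chunks[0]
    out_sites = list(first.sites)
    out_gt = [first.genotypes]
    out_post = [
        first.posterior if first.posterior is not None else np.ones(first.n_sites)
    ]
    out_imp = [
        first.imputed if first.imputed is not None else np.zeros(first.n_sites, bool)
    ]
    seen: dict = {s.key(): tuple(g) for s, g in zip(out_sites, chunks[0].genotypes)}
    for c in chunks[1:]:
        gt = c.genotypes.copy()
        votes_flip = votes_keep = 0
        for j, s in enumerate(c.sites):
            prev = seen.get(s.key())
            if prev is not None and gt[j, 0] != gt[j, 1] and prev[0] != prev[1]:
                if prev == tuple(gt[j]):
                    votes_keep += 1
                else:
                    votes_flip += 1
        if votes_flip + votes_keep == 0:
            _w.warn("chunk ligation without overlapping HETs: phase break")
        if votes_flip > votes_keep:
            gt = gt[:, ::-1]
        new = [j for j, s in enumerate(c.sites) if s.key() not in seen]
        for j, s in enumerate(c.sites):
            if s.key() not in seen:
                out_sites.append(s)
            seen[s.key()] = tuple(gt[j])
        out_gt.append(gt[new])
        out_post.append(c.posterior[new] if c.posterior is not None else np.ones(len(new)))
        out_imp.append(
            c.imputed[new] if c.imputed is not None else np.zeros(len(new), bool)
        )
    sites_sorted = sorted(range(len(out_sites)), key=lambda i: (out_sites[i].contig, out_sites[i].pos))
    gt_all = np.concatenate(out_gt)[sites_sorted]
    post_all = np.concatenate(out_post)[sites_sorted]
    imp_all = np.concatenate(out_imp)[sites_sorted]
    return PhasedCallset(
        [out_sites[i] for i in sites_sorted], gt_all, posterior=post_all, imputed=imp_all
    )
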