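"""Pair-angle distribution function (PADF) over (r, r′, Θ).

The PADF histograms pairs of interatomic vectors by their two lengths
and mutual angle, resolving three-body arrangements (vector pairs
sharing an atom — e.g. the tetrahedral ~109° nearest-neighbour angle of
ice, the 120° basal-plane hexagons, the 90° square arrangements) and
four-body arrangements (vector pairs sharing no atom — e.g. the c-axis
stacking contact at r ≈ 5.25 Å).  Oxygen-only input; with a single
species no form-factor scaling is needed.

Computation follows the supercell scheme: the structure is replicated
±1 cell in every axis, all interatomic vectors up to the probe distance
(default 10 Å, the RDF truncation) are taken from atoms of the central
cell, and vector pairs accumulate into the histogram in a seeded random
atom order.  Accumulation stops early once the cosine dissimilarity of
successive normalized volumes drops below a cutoff (default 1e-11): in
a periodic crystal every atom contributes a nearly identical pattern,
so convergence is reached after a handful of atoms, while disordered
frames run longer.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PADFVolume", "PeakTrack", "compute_padf", "slice_requal",
           "track_peaks"]


@dataclasses.dataclass
class PADFVolume:
    r_edges: np.ndarray          # Å
    theta_edges: np.ndarray      # degrees, covering [0, 180]
    three_body: np.ndarray       # (nr, nr, ntheta) counts, apex-sharing pairs
    four_body: np.ndarray        # (nr, nr, ntheta) counts, disjoint pairs
    time_fs: float = 0.0
    n_atoms: int = 0
    n_processed: int = 0
    converged: bool = False

    @property
    def counts(self) -> np.ndarray:
        """Combined three- + four-body histogram."""
        return self.three_body + self.four_body

    @property
    def r_centres(self):
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centres(self):
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


def _supercell_oxygens(positions, box):
    """±1-replicated positions; central-cell atoms come first."""
    shifts = [(0, 0, 0)] + [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    blocks = [positions + np.array(s) * box for s in shifts]
    return np.vstack(blocks)


def compute_padf(
    positions: np.ndarray,
    box: np.ndarray | None,
    r_max: float = 10.0,
    r_bin: float = 0.1,
    theta_bin_deg: float = 2.0,
    convergence_cutoff: float = 1e-11,
    seed: int = 0,
    include_four_body: bool = True,
    time_fs: float = 0.0,
) -> PADFVolume:
    """PADF of an oxygen-only configuration.

    Parameters
    ----------
    positions : (N, 3) oxygen coordinates, Å.
    box : orthorhombic box for ±1 supercell replication, or None for an
        isolated cluster.
    convergence_cutoff : stop accumulating when 1 − cos-similarity of the
        successive normalized volumes falls below this value.
    seed : randomized atom-processing order (reproducible).
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 3:
        raise ValueError("PADF requires at least 3 atoms")
    if box is not None:
        allpos = _supercell_oxygens(positions, np.asarray(box, dtype=float))
    else:
        allpos = positions

    r_edges = np.arange(0.0, r_max + r_bin, r_bin)
    # θ bins are centred on 0, Δ, 2Δ, ..., 180 so that the high-symmetry
    # angles of a lattice (60°, 90°, 109.47°, 120°, 180°) fall on bin
    # centres, not edges — edge-straddling would make otherwise identical
    # per-atom contributions flicker between bins and defeat the
    # convergence test
    theta_edges = np.arange(
        -theta_bin_deg / 2.0, 180.0 + theta_bin_deg, theta_bin_deg
    )
    nr = len(r_edges) - 1
    nth = len(theta_edges) - 1

    # vector blocks per central atom: displacement, length, endpoint id
    blocks = []
    for i in range(n):
        d = allpos - positions[i]
        r = np.linalg.norm(d, axis=1)
        keep = (r > 1e-9) & (r <= r_max)
        idx = np.flatnonzero(keep)
        blocks.append((d[idx], r[idx], idx))
    apex_ids = np.arange(n)  # central atoms are the first n supercell atoms

    all_vec = np.vstack([b[0] for b in blocks])
    all_len = np.concatenate([b[1] for b in blocks])
    all_end = np.concatenate([b[2] for b in blocks])
    all_apex = np.concatenate(
        [np.full(len(b[1]), i) for i, b in enumerate(blocks)]
    )
    inv_len = 1.0 / all_len
    r_bin_idx = np.minimum((all_len / r_bin).astype(int), nr - 1)

    three = np.zeros((nr, nr, nth))
    four = np.zeros((nr, nr, nth))
    prev_flat = None
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    processed = 0
    converged = False
    for i in order:
        vec_i, len_i, end_i = blocks[i]
        if len(len_i) == 0:
            processed += 1
            continue
        rb_i = np.minimum((len_i / r_bin).astype(int), nr - 1)
        # cosine of the mutual angle, every vector of atom i vs all vectors
        cosang = (vec_i @ all_vec.T) * inv_len[None, :] / len_i[:, None]
        np.clip(cosang, -1.0, 1.0, out=cosang)
        theta = np.degrees(np.arccos(cosang))
        tb = np.minimum(
            ((theta + theta_bin_deg / 2.0) / theta_bin_deg).astype(int), nth - 1
        )

        # endpoint sharing classification.  Three-body pairs are counted
        # only when the two vectors emanate from a common apex atom (the
        # angle is then the physical bond angle at that atom); pairs
        # sharing one atom in any other head/tail combination are the
        # same three-atom arrangements re-represented with supplementary
        # angles and are skipped to avoid double counting.  Pairs sharing
        # no atom form the four-body channel.
        share_apex = all_apex[None, :] == i
        share_end = end_i[:, None] == all_end[None, :]
        share_ae = end_i[:, None] == all_apex[None, :]
        share_ea = all_end[None, :] == i
        is_pair3 = share_apex & ~share_end
        is_pair4 = ~(share_apex | share_end | share_ae | share_ea)

        rb_j = np.broadcast_to(r_bin_idx[None, :], tb.shape)
        rb_ii = np.broadcast_to(rb_i[:, None], tb.shape)

        for sel, hist in ((is_pair3, three), (is_pair4, four)):
            if sel is is_pair4 and not include_four_body:
                continue
            a = rb_ii[sel]
            b = rb_j[sel]
            t = tb[sel]
            flat = (a * nr + b) * nth + t
            counts = np.bincount(flat, minlength=nr * nr * nth).reshape(
                nr, nr, nth
            ).astype(float)
            # symmetrize the (r, r') axes
            hist += counts + counts.transpose(1, 0, 2)

        processed += 1
        total = (three + four).ravel()
        norm = np.linalg.norm(total)
        if norm > 0 and prev_flat is not None:
            cos_sim = float(np.dot(total, prev_flat) / (norm * np.linalg.norm(prev_flat)))
            if 1.0 - cos_sim < convergence_cutoff:
                converged = True
                break
        prev_flat = total.copy()

    return PADFVolume(
        r_edges=r_edges,
        theta_edges=theta_edges,
        three_body=three,
        four_body=four,
        time_fs=time_fs,
        n_atoms=n,
        n_processed=processed,
        converged=converged,
    )


def slice_requal(volume: PADFVolume, channel: str = "both") -> np.ndarray:
    """r = r′ diagonal slice: the frequency of isosceles vector pairs.

    Returns an (nr, ntheta) map.  ``channel`` selects "three", "four" or
    "both".
    """
    src = {
        "both": volume.counts,
        "three": volume.three_body,
        "four": volume.four_body,
    }[channel]
    nr = src.shape[0]
    return src[np.arange(nr), np.arange(nr), :]


@dataclasses.dataclass
class PeakTrack:
    label: str
    times: np.ndarray
    intensity: np.ndarray        # normalized to 1 at t = 0
    locations: list              # per-time (r, theta) of the peak maximum
    terminated: bool = False


def track_peaks(
    volumes: list,
    initial_peaks: dict,
    tolerance: float = 0.5,
    box_half_r: float = 0.55,
    box_half_theta: float = 12.0,
    noise_floor_frac: float = 0.005,
    channel: str = "both",
) -> dict:
    """Track r = r′ PADF peaks through a time series of volumes.

    ``initial_peaks`` maps labels to (r, Θ) coordinates at t = 0.  At each
    time step the local uncorrelated background (the median of the search
    box) is subtracted, the integration region is re-derived as the bins
    exceeding ``tolerance`` times the current background-corrected local
    maximum, and the integrated excess counts are normalized to the
    t = 0 value.  Background subtraction matters for the four-body
    channel, whose diffuse pair background persists through the melt and
    would otherwise mask the decay of the coherent feature.  A track
    whose corrected maximum falls below ``noise_floor_frac`` of its
    t = 0 value is terminated rather than extrapolated.
    """
    tracks = {}
    for label, (r0, th0) in initial_peaks.items():
        times, values, locs = [], [], []
        r_c, th_c = r0, th0
        m0 = None
        terminated = False
        for vol in volumes:
            s = slice_requal(vol, channel=channel).astype(float)
            total = s.sum()
            s = s / total if total > 0 else s
            r = vol.r_centres
            th = vol.theta_centres
            rm = (r >= r_c - box_half_r) & (r <= r_c + box_half_r)
            tm = (th >= th_c - box_half_theta) & (th <= th_c + box_half_theta)
            sub = s[np.ix_(rm, tm)]
            if sub.size == 0:
                terminated = True
                break
            bg = float(np.median(sub))
            m = sub.max() - bg
            if m0 is None:
                m0 = m
            if m < noise_floor_frac * m0 or m <= 0:
                terminated = True
                break
            region = sub >= bg + tolerance * m
            integral = float(np.sum(sub[region] - bg))
            ir, it = np.unravel_index(np.argmax(sub), sub.shape)
            r_c = float(r[rm][ir])
            th_c = float(th[tm][it])
            times.append(vol.time_fs)
            values.append(integral)
            locs.append((r_c, th_c))
        values = np.array(values)
        if len(values) and values[0] > 0:
            values = values / values[0]
        tracks[label] = PeakTrack(
            label=label,
            times=np.array(times),
            intensity=values,
            locations=locs,
            terminated=terminated,
        )
    return tracks
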