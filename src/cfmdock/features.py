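"""Template-style pair featurization of a (noisy) complex structure.

A structure of total length L is encoded as a set of L x L pair features in
the lineage of the AlphaFold template module: a one-hot CB distogram, unit
displacement vectors expressed in the row residue's backbone frame, CB and
frame masks, residue-identity pairs, clipped relative sequence positions,
and (for the conditioning stream) Fourier features of the flow time t.

Every geometric feature is expressed in local frames or as a distance, so
the whole feature set is invariant under global rigid motion of the input.
Inter-chain entries are computed like intra-chain ones — the inter-chain
block is deliberately *not* masked out, which is what lets the denoiser see
the current relative pose of the two chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import backbone_frames
from .residues import AA_INDEX, ATOM_INDEX, N_AA
from .structio import ComplexConformation

#: default distogram binning: 38 bins spanning 3.25 to 50.75 Angstrom
#: (the AlphaFold template convention); values outside fall into the first
#: or last bin
DEFAULT_DISTOGRAM_BINS: np.ndarray = np.linspace(3.25, 50.75, 39)

#: number of Fourier time-embedding features
N_TIME_FEATURES = 16

#: relative sequence offsets are clipped to +/- this many residues
REL_POSITION_CLIP = 32

__all__ = [
    "PairFeatureSet",
    "distogram",
    "unit_vectors",
    "time_embedding",
    "assemble_features",
    "DEFAULT_DISTOGRAM_BINS",
]


@dataclass
class PairFeatureSet:
    """L x L pair features plus optional time conditioning.

    ``residue_type_pair`` is the (row, column) one-hot pair of identities,
    zeroed when sequence embedding is disabled; ``rel_position`` carries the
    clipped signed within-chain offset (scaled to [-1, 1]) and a same-chain
    indicator.
    """

    distogram: np.ndarray  # (L, L, B) one-hot
    unit_vectors: np.ndarray  # (L, L, 3), row-frame coordinates
    cb_mask: np.ndarray  # (L, L) bool
    frame_mask: np.ndarray  # (L, L) bool
    residue_type_pair: np.ndarray  # (L, L, 2 * N_AA)
    rel_position: np.ndarray  # (L, L, 2)
    time_embedding: np.ndarray | None = None  # (N_TIME_FEATURES,)

    @property
    def length(self) -> int:
        return self.distogram.shape[0]

    @property
    def n_channels(self) -> int:
        n = (
            self.distogram.shape[-1]
            + 3
            + 2
            + self.residue_type_pair.shape[-1]
            + self.rel_position.shape[-1]
        )
        if self.time_embedding is not None:
            n += len(self.time_embedding)
        return n

    def concat(self) -> np.ndarray:
        """All channels stacked into one (L, L, C) float32 tensor."""
        L = self.length
        parts = [
            self.distogram,
            self.unit_vectors,
            self.cb_mask[..., None].astype(np.float32),
            self.frame_mask[..., None].astype(np.float32),
            self.residue_type_pair,
            self.rel_position,
        ]
        if self.time_embedding is not None:
            parts.append(np.broadcast_to(self.time_embedding, (L, L, len(self.time_embedding))))
        return np.concatenate([p.astype(np.float32) for p in parts], axis=-1)


def distogram(
    cb: np.ndarray,
    mask: np.ndarray,
    bins: np.ndarray = DEFAULT_DISTOGRAM_BINS,
) -> np.ndarray:
    """One-hot binned pairwise CB distances.

    Distances below the first edge go to the first bin and above the last
    edge to the last bin; the diagonal (d = 0) thus lands in the first bin.
    Pairs with a missing CB are all-zero.
    """
    bins = np.asarray(bins, dtype=float)
    if not np.all(np.diff(bins) > 0):
        raise ValueError("distogram bin edges must be strictly increasing")
    n_bins = len(bins) - 1
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    idx = np.clip(np.searchsorted(bins, d, side="right") - 1, 0, n_bins - 1)
    out = np.eye(n_bins, dtype=np.float32)[idx]
    pair_mask = mask[:, None] & mask[None, :]
    out[~pair_mask] = 0.0
    return out


def unit_vectors(
    frame_rotations: np.ndarray,
    frame_valid: np.ndarray,
    ca: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-residue CA displacement directions in the row residue's frame.

    Entry (i, j) is ``F_i^T (ca_j - ca_i) / |ca_j - ca_i|``; the diagonal and
    pairs with an invalid row frame or coincident CAs are zero and masked.
    """
    L = len(ca)
    diff = ca[None, :, :] - ca[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    ok = (dist > 1e-6) & frame_valid[:, None]
    np.fill_diagonal(ok, False)
    safe = np.where(dist[..., None] > 1e-6, dist[..., None], 1.0)
    # row-frame projection: F_i columns are the frame axes
    local = np.einsum("iab,ija->ijb", frame_rotations, diff / safe)
    local[~ok] = 0.0
    return local.astype(np.float32), ok


def time_embedding(t: float, n_features: int = N_TIME_FEATURES) -> np.ndarray:
    """Fourier features of the flow time: sin/cos at dyadic frequencies."""
    k = np.arange(n_features // 2)
    angles = np.pi * (2.0**k) * t
    return np.concatenate([np.sin(angles), np.cos(angles)]).astype(np.float32)


def assemble_features(
    x: ComplexConformation,
    t: float,
    use_seq_embed: bool = True,
    bins: np.ndarray = DEFAULT_DISTOGRAM_BINS,
) -> tuple[PairFeatureSet, PairFeatureSet]:
    """Build the (noisy, conditioning) feature pair for a complex.

    Both sets share the positional/structural channels (inter-chain entries
    included); the conditioning set additionally carries the time embedding.
    ``use_seq_embed=False`` zeroes the residue-identity channels without
    changing any shape — the sequence-free ablation toggle.
    """
    chains = x.chains
    L = len(x)
    cb_idx, ca_idx = ATOM_INDEX["CB"], ATOM_INDEX["CA"]

    cb = np.concatenate([c.coords[:, cb_idx] for c in chains])
    cb_present = np.concatenate([c.atom_mask[:, cb_idx] for c in chains])
    ca = np.concatenate([c.coords[:, ca_idx] for c in chains])

    rot_list, valid_list = [], []
    for c in chains:
        frames = backbone_frames(
            c.n, c.ca, c.c, atom_valid=c.atom_mask[:, [0, 1, 2]].all(axis=1)
        )
        rot_list.append(frames.rotations)
        valid_list.append(frames.valid)
    rotations = np.concatenate(rot_list)
    frame_valid = np.concatenate(valid_list)

    disto = distogram(cb, cb_present, bins)
    uv, uv_mask = unit_vectors(rotations, frame_valid, ca)

    aa_idx = np.concatenate(
        [[AA_INDEX[a] for a in c.sequence] for c in chains]
    ).astype(int)
    one_hot = np.eye(N_AA, dtype=np.float32)[aa_idx]
    if not use_seq_embed:
        one_hot = np.zeros_like(one_hot)
    rt_pair = np.concatenate(
        [
            np.broadcast_to(one_hot[:, None, :], (L, L, N_AA)),
            np.broadcast_to(one_hot[None, :, :], (L, L, N_AA)),
        ],
        axis=-1,
    )

    chain_of = np.concatenate([np.full(len(c), k) for k, c in enumerate(chains)])
    pos_in_chain = np.concatenate([np.arange(len(c)) for c in chains])
    same_chain = chain_of[:, None] == chain_of[None, :]
    offset = np.clip(
        pos_in_chain[None, :] - pos_in_chain[:, None],
        -REL_POSITION_CLIP,
        REL_POSITION_CLIP,
    ).astype(np.float32)
    offset[~same_chain] = 0.0
    rel = np.stack(
        [offset / REL_POSITION_CLIP, same_chain.astype(np.float32)], axis=-1
    )

    cb_pair_mask = cb_present[:, None] & cb_present[None, :]
    base = dict(
        distogram=disto,
        unit_vectors=uv,
        cb_mask=cb_pair_mask,
        frame_mask=uv_mask,
        residue_type_pair=rt_pair,
        rel_position=rel,
    )
    noisy = PairFeatureSet(**base, time_embedding=None)
    cond = PairFeatureSet(**{k: v.copy() for k, v in base.items()}, time_embedding=time_embedding(t))
    return noisy, cond
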