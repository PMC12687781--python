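"""Docking metrics and benchmark statistics.

Implements the DockQ family of metrics on backbone+CB structures:

* ``fnat`` — fraction of native inter-chain residue contacts (any
  represented-atom distance < 5 A) reproduced by the model;
* ``iRMSD`` — backbone RMSD over native interface residues (any atom
  within 10 A of the other chain) after superposition on those residues;
* ``LRMSD`` — ligand backbone RMSD after receptor-backbone superposition;
* ``DockQ = (fnat + 1/(1+(iRMSD/1.5)^2) + 1/(1+(LRMSD/8.5)^2)) / 3`` with
  quality classes acceptable > 0.23, medium > 0.49, high > 0.80 (strict
  inequalities);
* ``ps-iRMSD`` — per-subunit interface RMSD after aligning each subunit
  individually, isolating internal deformation from rigid-body motion.

Represented atoms are {N, CA, C, O, CB}: the toy structures carry no
side chains, so contacts are computed on this set while the DockQ
constants are kept at their published values.

Benchmark statistics: Top-k and oracle success rates with percentile
bootstrap confidence intervals (10,000 resamples over targets) and the
one-sided Wilcoxon signed-rank test for paired comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .geometry import kabsch_align
from .residues import ATOM_INDEX, BACKBONE_ATOMS
from .structio import ComplexConformation

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 5.0  # A, any represented atom
INTERFACE_CUTOFF = 10.0  # A, interface-residue definition
IRMSD_SCALE = 1.5  # A
LRMSD_SCALE = 8.5  # A
THRESHOLDS = {"acceptable": 0.23, "medium": 0.49, "high": 0.80}

_BB = [ATOM_INDEX[a] for a in BACKBONE_ATOMS]

__all__ = [
    "DockQResult",
    "PredictionSet",
    "native_contacts",
    "dockq",
    "dockq_score",
    "quality_class",
    "ps_irmsd",
    "success_rates",
    "bootstrap_ci",
    "paired_one_sided_test",
    "THRESHOLDS",
]


@dataclass(frozen=True)
class DockQResult:
    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    quality: str


@dataclass
class PredictionSet:
    """Ranked predictions for one target with their quality scores.

    ``predictions`` is kept sorted by confidence descending (ties broken by
    insertion order); ``dockq_scores`` aligns with it.
    """

    target_id: str
    confidences: np.ndarray
    dockq_scores: np.ndarray
    results: list[DockQResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, dtype=float)
        self.dockq_scores = np.asarray(self.dockq_scores, dtype=float)
        if len(self.confidences) != len(self.dockq_scores) or len(self.confidences) == 0:
            raise ValueError("need matching, non-empty confidence and score arrays")
        order = np.argsort(-self.confidences, kind="stable")
        self.confidences = self.confidences[order]
        self.dockq_scores = self.dockq_scores[order]
        if self.results:
            self.results = [self.results[i] for i in order]

    def __len__(self) -> int:
        return len(self.confidences)

    def best_of_top(self, k: int) -> float:
        if k > len(self):
            logger.warning(
                "top-%d requested for %d predictions; clamping", k, len(self)
            )
            k = len(self)
        return float(self.dockq_scores[:k].max())

    @property
    def oracle(self) -> float:
        return float(self.dockq_scores.max())


# ---------------------------------------------------------------------------
# contacts and DockQ
# ---------------------------------------------------------------------------


def _present_atoms_per_residue(conf: ComplexConformation, chain) -> tuple[np.ndarray, np.ndarray]:
    """Flat atom coordinates plus the residue index of every present atom."""
    coords = chain.coords[chain.atom_mask]
    res_idx = np.repeat(np.arange(len(chain)), chain.atom_mask.sum(axis=1))
    return coords, res_idx


def _residue_pair_contacts(
    model: ComplexConformation, cutoff: float
) -> set[tuple[int, int]]:
    rc, ri = _present_atoms_per_residue(model, model.receptor)
    lc, li = _present_atoms_per_residue(model, model.ligand)
    close = cdist(rc, lc) < cutoff
    pairs = set(zip(ri[np.nonzero(close)[0]].tolist(), li[np.nonzero(close)[1]].tolist()))
    return pairs


def native_contacts(
    native: ComplexConformation, cutoff: float = CONTACT_CUTOFF
) -> set[tuple[int, int]]:
    """Native inter-chain residue contacts (receptor index, ligand index).

    A pair is in contact when any represented atom of one residue lies
    within ``cutoff`` of any represented atom of the other.
    """
    pairs = _residue_pair_contacts(native, cutoff)
    if not pairs:
        raise ValueError("structures share no inter-chain contacts; not a complex")
    return pairs


def _interface_residues(native: ComplexConformation) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of native interface residues (10 A any-atom rule)."""
    rc, ri = _present_atoms_per_residue(native, native.receptor)
    lc, li = _present_atoms_per_residue(native, native.ligand)
    close = cdist(rc, lc) < INTERFACE_CUTOFF
    rec_mask = np.zeros(len(native.receptor), dtype=bool)
    lig_mask = np.zeros(len(native.ligand), dtype=bool)
    rec_mask[np.unique(ri[np.any(close, axis=1)])] = True
    lig_mask[np.unique(li[np.any(close, axis=0)])] = True
    return rec_mask, lig_mask


def _backbone(chain, res_mask: np.ndarray | None = None) -> np.ndarray:
    coords = chain.coords[:, _BB, :]
    if res_mask is not None:
        coords = coords[res_mask]
    return coords.reshape(-1, 3)


def dockq_score(fnat: float, irmsd: float, lrmsd: float) -> float:
    """The DockQ combination formula."""
    return (
        fnat
        + 1.0 / (1.0 + (irmsd / IRMSD_SCALE) ** 2)
        + 1.0 / (1.0 + (lrmsd / LRMSD_SCALE) ** 2)
    ) / 3.0


def quality_class(dockq_value: float) -> str:
    """Strict-threshold quality class (a score of exactly 0.23 is incorrect)."""
    if dockq_value > THRESHOLDS["high"]:
        return "high"
    if dockq_value > THRESHOLDS["medium"]:
        return "medium"
    if dockq_value > THRESHOLDS["acceptable"]:
        return "acceptable"
    return "incorrect"


def dockq(model: ComplexConformation, native: ComplexConformation) -> DockQResult:
    """DockQ of ``model`` against ``native`` (shared chain topology required)."""
    if [len(c) for c in model.chains] != [len(c) for c in native.chains]:
        raise ValueError("model and native do not share chain topology")

    native_pairs = native_contacts(native)
    model_pairs = _residue_pair_contacts(model, CONTACT_CUTOFF)
    fnat = len(native_pairs & model_pairs) / len(native_pairs)

    rec_mask, lig_mask = _interface_residues(native)
    model_iface = np.concatenate(
        [_backbone(model.receptor, rec_mask), _backbone(model.ligand, lig_mask)]
    )
    native_iface = np.concatenate(
        [_backbone(native.receptor, rec_mask), _backbone(native.ligand, lig_mask)]
    )
    _, irmsd = kabsch_align(model_iface, native_iface)

    rec_t, _ = kabsch_align(_backbone(model.receptor), _backbone(native.receptor))
    lig_aligned = rec_t.apply(_backbone(model.ligand))
    lrmsd = float(
        np.sqrt(np.mean(np.sum((lig_aligned - _backbone(native.ligand)) ** 2, axis=1)))
    )

    score = dockq_score(fnat, irmsd, lrmsd)
    return DockQResult(
        fnat=float(fnat),
        irmsd=float(irmsd),
        lrmsd=float(lrmsd),
        dockq=float(score),
        quality=quality_class(score),
    )


def ps_irmsd(
    a: ComplexConformation,
    b: ComplexConformation,
    native: ComplexConformation,
    align_scope: str = "subunit",
) -> tuple[float, float]:
    """Per-subunit interface RMSD between ``a`` and ``b``.

    Interface residues come from ``native`` (10 A rule).  Each subunit of
    ``a`` is individually superposed onto its counterpart in ``b`` — on all
    its backbone atoms by default, or on interface backbone only with
    ``align_scope='interface'`` — and the RMSD is then measured over the
    interface residues' backbone atoms.  Rigid motion of a whole subunit
    therefore contributes nothing; only internal deformation does.

    Returns (receptor value, ligand value) in Angstrom.
    """
    if align_scope not in ("subunit", "interface"):
        raise ValueError("align_scope must be 'subunit' or 'interface'")
    rec_mask, lig_mask = _interface_residues(native)
    if not rec_mask.any() or not lig_mask.any():
        raise ValueError("empty native interface")
    values = []
    for chain_a, chain_b, mask in (
        (a.receptor, b.receptor, rec_mask),
        (a.ligand, b.ligand, lig_mask),
    ):
        fit_mask = mask if align_scope == "interface" else None
        transform, _ = kabsch_align(
            _backbone(chain_a, fit_mask), _backbone(chain_b, fit_mask)
        )
        moved = transform.apply(_backbone(chain_a, mask))
        target = _backbone(chain_b, mask)
        values.append(float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))))
    return values[0], values[1]


# ---------------------------------------------------------------------------
# success rates and statistics
# ---------------------------------------------------------------------------


def bootstrap_ci(
    successes: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap of a success-rate mean over targets.

    Returns (mean, lower, upper) at the given level.
    """
    rng = rng or np.random.default_rng(0)
    successes = np.asarray(successes, dtype=float)
    n = len(successes)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = successes[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(successes.mean()), float(lo), float(hi)


def success_rates(
    sets: list[PredictionSet],
    ks: tuple[int, ...] = (1, 5),
    threshold: float = THRESHOLDS["acceptable"],
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Top-k and oracle success rates with bootstrap CIs.

    A target succeeds at level k when the best DockQ among its top-k ranked
    predictions exceeds ``threshold`` (strictly); the oracle uses all
    predictions.  CIs are 95% percentile bootstrap over targets with
    ``n_boot`` resamples.
    """
    if not sets:
        raise ValueError("no prediction sets given")
    rng = rng or np.random.default_rng(0)
    out = {}
    for label, scores in [
        (f"top{k}", np.array([ps.best_of_top(k) for ps in sets])) for k in ks
    ] + [("oracle", np.array([ps.oracle for ps in sets]))]:
        successes = (scores > threshold).astype(float)
        mean, lo, hi = bootstrap_ci(successes, n_boot=n_boot, rng=rng)
        out[label] = {"rate": mean, "ci_low": lo, "ci_high": hi}
    return out


def paired_one_sided_test(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value for median(x - y) < 0.

    Zero differences are dropped (the standard convention); if every
    difference is zero the test is undefined and p = 1 is returned with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise ValueError("need paired 1-D samples of equal length >= 5")
    if np.all(x == y):
        warnings.warn("all paired differences are zero; p-value undefined, returning 1.0")
        return 1.0
    res = sps.wilcoxon(x, y, alternative="less", zero_method="wilcox")
    return float(res.pvalue)
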