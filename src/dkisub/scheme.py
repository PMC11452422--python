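"""Multi-shell gradient scheme design, ordering, and subsampling.

A diffusion MRI acquisition is described by a :class:`GradientScheme`: one
unit gradient direction and one b-value per volume, plus the order in which
the volumes are acquired.  Direction sets are optimized by the bipolar
electrostatic repulsion model (EEM): each direction and its antipode act as
charged particles on the unit sphere and the Coulomb-like energy is
minimized, which spreads the sampled orientations uniformly.  Angular
resolution of a direction set is measured by its covering radius — the
smallest pairwise line-angle (spherical-codes criterion).

Three subsampling families model what happens when an acquisition is
interrupted or deliberately shortened:

* ``Opt_EEM`` — truncation of an incrementally ordered scheme whose every
  prefix is itself well spread (``order_incremental_eem`` +
  ``subsample_eem``);
* ``Opt_SC`` — nested subsets chosen to maximize the covering radius
  (``subsample_sc``), built sequentially so each level is a subset of the
  previous one;
* ``Random_TRUNC`` — a seeded random shuffle-and-truncate reference
  (``subsample_random``).

The optimized strategies always retain every b = 0 volume; random
truncation cuts the shuffled scheme blindly, b = 0 volumes included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GradientScheme",
    "SubsetSpec",
    "SingularConfigurationError",
    "InfeasibleSubsetError",
    "IllPosedSchemeError",
    "subset_sizes",
    "electrostatic_energy",
    "covering_radius",
    "generate_multishell_scheme",
    "order_incremental_eem",
    "subsample_eem",
    "subsample_sc",
    "subsample_random",
]

B0_THRESHOLD = 50.0  # s/mm²; b-values below this count as non-diffusion-weighted


class SingularConfigurationError(ValueError):
    """A pair of directions is coincident or antipodal (infinite EEM energy)."""


class InfeasibleSubsetError(ValueError):
    """A requested subset is too small to support tensor estimation."""


class IllPosedSchemeError(ValueError):
    """The scheme cannot support the requested model fit."""


# ---------------------------------------------------------------------------
# Scheme container


@dataclass(frozen=True)
class GradientScheme:
    """An ordered list of (direction, b-value) volumes with shell labels.

    Volumes are stored in acquisition order.  ``directions`` holds unit
    vectors for diffusion-weighted volumes and zero vectors for b = 0
    volumes.  ``shell_id`` is 0 for b = 0 and 1..K for the diffusion shells
    in ascending b.  ``source_index`` maps each volume back to the scheme
    this one was derived from (identity for freshly generated schemes),
    which is what lets a subset extract its volumes from an already
    acquired/simulated full dataset.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    shell_id: np.ndarray
    order: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        bvalues = np.asarray(self.bvalues, dtype=float)
        shell_id = np.asarray(self.shell_id, dtype=int)
        n = len(bvalues)
        if directions.shape != (n, 3):
            raise ValueError("directions must be (N, 3)")
        order = self.order
        order = np.arange(n) if order is None else np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of 0..N-1")
        src = self.source_index
        src = np.arange(n) if src is None else np.asarray(src, dtype=int)
        dw = bvalues > B0_THRESHOLD
        norms = np.linalg.norm(directions, axis=1)
        # tolerance admits 6-decimal fixed-point gradient-table round-trips;
        # freshly generated schemes are unit to ~1e-12
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        if np.any(norms[~dw] > 1e-12):
            raise ValueError("b = 0 volumes must carry a zero vector")
        # equal b-values share a shell label
        for b in np.unique(bvalues):
            ids = np.unique(shell_id[bvalues == b])
            if len(ids) != 1:
                raise ValueError("volumes with equal b-value must share a shell_id")
        for name, value in [
            ("directions", directions), ("bvalues", bvalues),
            ("shell_id", shell_id), ("order", order), ("source_index", src),
        ]:
            value.setflags(write=False)
            object.__setattr__(self, name, value)

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvalues > B0_THRESHOLD

    @property
    def shells(self) -> list[int]:
        """Diffusion shell labels (excluding b = 0), ascending b."""
        ids = sorted(set(self.shell_id[self.dw_mask].tolist()))
        return ids

    def shell_bvalue(self, shell: int) -> float:
        return float(self.bvalues[self.shell_id == shell][0])

    def shell_indices(self, shell: int) -> np.ndarray:
        """Volume indices of a shell, in acquisition order."""
        return np.flatnonzero(self.shell_id == shell)

    def take(self, indices: np.ndarray) -> "GradientScheme":
        """New scheme from a volume subset, acquisition order preserved."""
        indices = np.sort(np.asarray(indices, dtype=int))
        return GradientScheme(
            directions=self.directions[indices],
            bvalues=self.bvalues[indices],
            shell_id=self.shell_id[indices],
            order=None,
            source_index=self.source_index[indices],
        )

    def rebase(self) -> "GradientScheme":
        """Copy with identity ``source_index``: this scheme becomes the
        reference that later subsets index into."""
        return GradientScheme(
            directions=self.directions,
            bvalues=self.bvalues,
            shell_id=self.shell_id,
        )

    def reorder(self, new_positions: np.ndarray) -> "GradientScheme":
        """Rearrange volumes so volume i is acquired at ``new_positions[i]``."""
        perm = np.argsort(np.asarray(new_positions, dtype=int))
        return GradientScheme(
            directions=self.directions[perm],
            bvalues=self.bvalues[perm],
            shell_id=self.shell_id[perm],
            order=None,
            source_index=self.source_index[perm],
        )


@dataclass(frozen=True)
class SubsetSpec:
    """Retained fraction and the per-shell direction counts it implies."""

    fraction_retained: float
    per_shell_counts: dict

    @classmethod
    def from_scheme(cls, scheme: GradientScheme, fraction: float) -> "SubsetSpec":
        counts = {
            s: subset_sizes(len(scheme.shell_indices(s)), fraction)
            for s in scheme.shells
        }
        return cls(fraction_retained=fraction, per_shell_counts=counts)

    def validate_against(self, scheme: GradientScheme) -> None:
        for s, c in self.per_shell_counts.items():
            avail = len(scheme.shell_indices(s))
            if c > avail:
                raise InfeasibleSubsetError(
                    f"shell {s}: requested {c} directions but only {avail} available"
                )


# ---------------------------------------------------------------------------
# Elementary quality measures


def subset_sizes(n_dirs: int, fraction: float) -> int:
    """Number of directions retained when keeping ``fraction`` of a shell.

    Round-half-up to the nearest integer; fewer than 6 directions cannot
    support tensor estimation and raises :class:`InfeasibleSubsetError`.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_dirs < 1:
        raise ValueError("n_dirs must be positive")
    count = int(np.floor(fraction * n_dirs + 0.5))
    if count < 6:
        raise InfeasibleSubsetError(
            f"{fraction:.0%} of {n_dirs} directions leaves {count} < 6"
        )
    return count


def _as_unit_directions(directions) -> np.ndarray:
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    if u.shape[0] < 2:
        raise ValueError("need at least 2 directions")
    norms = np.linalg.norm(u, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit norm")
    return u


def electrostatic_energy(directions) -> float:
    """Bipolar electrostatic (Coulomb) energy of a direction set.

    Each direction contributes together with its antipode:
    E = Σ_{i<j} 1/‖uᵢ−uⱼ‖ + 1/‖uᵢ+uⱼ‖.
    """
    u = _as_unit_directions(directions)
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    nd = np.linalg.norm(diff, axis=-1)
    ns = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(len(u), k=1)
    nd, ns = nd[iu], ns[iu]
    if np.any(nd < 1e-12) or np.any(ns < 1e-12):
        raise SingularConfigurationError("coincident or antipodal direction pair")
    return float(np.sum(1.0 / nd + 1.0 / ns))


def covering_radius(directions) -> float:
    """Smallest pairwise line-angle of a direction set, in degrees.

    Antipodally symmetric (a direction and its negation are the same
    sampling orientation), so the result lies in [0°, 90°].
    """
    u = _as_unit_directions(directions)
    g = np.abs(u @ u.T)
    iu = np.triu_indices(len(u), k=1)
    return float(np.degrees(np.arccos(np.clip(g[iu], -1.0, 1.0))).min())


# ---------------------------------------------------------------------------
# EEM generation

def _pair_weights(shell_of: np.ndarray, coupling: float) -> np.ndarray:
    """Pair weight matrix: 1 for same-shell pairs plus `coupling` for all pairs."""
    same = shell_of[:, None] == shell_of[None, :]
    w = same.astype(float) + coupling
    np.fill_diagonal(w, 0.0)
    return w


def _energy_and_grad(x: np.ndarray, shell_of: np.ndarray, w: np.ndarray):
    """Weighted bipolar energy and gradient w.r.t. unnormalized vectors."""
    v = x.reshape(-1, 3)
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    u = v / vn
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    nd = np.linalg.norm(diff, axis=-1)
    ns = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(nd, 1.0)
    nd = np.maximum(nd, 1e-9)
    ns = np.maximum(ns, 1e-9)
    energy = 0.5 * np.sum(w * (1.0 / nd + 1.0 / ns))
    # dE/du_i = Σ_j w_ij [ −(u_i−u_j)/nd³ − (u_i+u_j)/ns³ ]
    gd = -(w / nd**3)[:, :, None] * diff - (w / ns**3)[:, :, None] * summ
    grad_u = gd.sum(axis=1)
    # chain rule through normalization: du/dv = (I − u uᵀ)/|v|
    grad_v = (grad_u - u * np.sum(grad_u * u, axis=1, keepdims=True)) / vn
    return energy, grad_v.ravel()


def generate_multishell_scheme(
    n_per_shell: dict,
    bvalues: dict,
    n_b0: int = 8,
    seed: int = 0,
    n_restarts: int = 20,
    coupling: float = 0.5,
    maxiter: int = 1000,
) -> GradientScheme:
    """Generate an EEM-optimized multi-shell scheme.

    Directions of every shell are jointly optimized to minimize the sum of
    per-shell bipolar electrostatic energies plus ``coupling`` times the
    energy of the union of all shells, by L-BFGS local descent from
    ``n_restarts`` seeded random starts (best energy kept).  The returned
    scheme lists the b = 0 volumes first and the shells in ascending b; use
    :func:`order_incremental_eem` for an interruption-robust ordering.
    """
    shells = sorted(n_per_shell, key=lambda s: bvalues[s])
    counts = [n_per_shell[s] for s in shells]
    if any(c < 6 for c in counts):
        raise InfeasibleSubsetError("each shell needs at least 6 directions")
    shell_of = np.repeat(np.arange(len(shells)), counts)
    w = _pair_weights(shell_of, coupling)
    rng = np.random.default_rng(seed)
    best = None
    best_energy = np.inf
    for _ in range(n_restarts):
        x0 = rng.standard_normal((len(shell_of), 3)).ravel()
        res = minimize(
            _energy_and_grad, x0, args=(shell_of, w), jac=True,
            method="L-BFGS-B", options={"maxiter": maxiter},
        )
        if not res.success and res.status != 1:  # status 1 = maxiter reached
            warnings.warn(f"EEM optimization did not converge: {res.message}")
        if res.fun < best_energy:
            best_energy = res.fun
            best = res.x
    u = best.reshape(-1, 3)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    dirs = [np.zeros((n_b0, 3))]
    bvals = [np.zeros(n_b0)]
    sid = [np.zeros(n_b0, dtype=int)]
    for k, s in enumerate(shells):
        dirs.append(u[shell_of == k])
        bvals.append(np.full(counts[k], float(bvalues[s])))
        sid.append(np.full(counts[k], k + 1, dtype=int))
    return GradientScheme(
        directions=np.vstack(dirs),
        bvalues=np.concatenate(bvals),
        shell_id=np.concatenate(sid),
    )


# ---------------------------------------------------------------------------
# Incremental ordering (Opt_EEM)


def order_incremental_eem(
    scheme: GradientScheme, coupling: float = 0.5
) -> GradientScheme:
    """Reorder a scheme so every prefix is balanced and well spread.

    Diffusion-weighted volumes are added one at a time: at each step the
    shell whose prefix count lags its full-scheme proportion the most is
    chosen (largest deficit; ties go to the lower shell label), and within
    that shell the direction adding the least bipolar electrostatic energy
    (same-shell plus ``coupling`` × cross-shell pair terms) to the prefix is
    appended.  Ties go to the lowest original acquisition index.  b = 0
    volumes are interleaved evenly, the first volume being b = 0.

    Truncating the result at any point leaves per-shell proportions within
    ±1 of the full scheme's — the Opt_EEM property.
    """
    dw_idx = np.flatnonzero(scheme.dw_mask)
    b0_idx = np.flatnonzero(~scheme.dw_mask)
    shells = scheme.shells
    props = {s: len(scheme.shell_indices(s)) / len(dw_idx) for s in shells}
    remaining = {s: list(scheme.shell_indices(s)) for s in shells}
    placed: list[int] = []
    counts = {s: 0 for s in shells}
    u_all = scheme.directions

    def added_energy(cand: int, placed_idx: list[int]) -> float:
        if not placed_idx:
            return 0.0
        p = u_all[placed_idx]
        c = u_all[cand]
        nd = np.linalg.norm(p - c, axis=1)
        ns = np.linalg.norm(p + c, axis=1)
        nd = np.maximum(nd, 1e-12)
        ns = np.maximum(ns, 1e-12)
        same = scheme.shell_id[placed_idx] == scheme.shell_id[cand]
        wts = same.astype(float) + coupling
        return float(np.sum(wts * (1.0 / nd + 1.0 / ns)))

    n_dw = len(dw_idx)
    for step in range(n_dw):
        deficits = [
            ((step + 1) * props[s] - counts[s], -s)
            for s in shells if remaining[s]
        ]
        shell = -max(deficits)[1]
        cands = remaining[shell]
        costs = [added_energy(c, placed) for c in cands]
        pick = int(np.argmin(costs))  # argmin takes the first = lowest index
        placed.append(cands.pop(pick))
        counts[shell] += 1

    # interleave b0 volumes evenly, first volume a b0
    n_total = scheme.n_volumes
    b0_slots = [int(np.floor(k * n_total / len(b0_idx))) for k in range(len(b0_idx))]
    new_positions = np.empty(n_total, dtype=int)
    dw_slots = [p for p in range(n_total) if p not in set(b0_slots)]
    for vol, slot in zip(b0_idx, b0_slots):
        new_positions[vol] = slot
    for vol, slot in zip(placed, dw_slots):
        new_positions[vol] = slot
    return scheme.reorder(new_positions)


def subsample_eem(scheme: GradientScheme, spec: SubsetSpec) -> GradientScheme:
    """Opt_EEM subset: per-shell prefix truncation of an ordered scheme.

    Keeps the first ``per_shell_counts[s]`` diffusion-weighted volumes of
    each shell in acquisition order plus every b = 0 volume — equivalent to
    stopping an :func:`order_incremental_eem`-ordered acquisition early.
    """
    spec.validate_against(scheme)
    keep = list(np.flatnonzero(~scheme.dw_mask))
    for s, c in spec.per_shell_counts.items():
        keep.extend(scheme.shell_indices(s)[:c])
    return scheme.take(np.array(keep))


# ---------------------------------------------------------------------------
# Spherical-codes subsampling (Opt_SC)


def _sc_objective(angle: np.ndarray, shell_sets: list[np.ndarray]) -> float:
    """0.5 × mean per-shell covering radius + 0.5 × union covering radius."""
    per_shell = []
    for idx in shell_sets:
        sub = angle[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        per_shell.append(sub[iu].min())
    union = np.concatenate(shell_sets)
    sub = angle[np.ix_(union, union)]
    iu = np.triu_indices(len(union), k=1)
    return 0.5 * float(np.mean(per_shell)) + 0.5 * float(sub[iu].min())


def subsample_sc(
    scheme: GradientScheme,
    spec: SubsetSpec,
    previous: GradientScheme | None = None,
    max_passes: int = 50,
) -> GradientScheme:
    """Opt_SC subset: maximize covering radius by greedy removal + exchange.

    Selects ``spec.per_shell_counts`` directions per shell from ``previous``
    (enforcing nesting when subsets are built sequentially) or from
    ``scheme``.  The objective is 0.5 × mean per-shell covering radius +
    0.5 × covering radius of the union of shells.  Directions are removed
    greedily (each removal the one that maximizes the objective), then
    refined by kept↔dropped pairwise exchanges within each shell until no
    swap improves the objective.  Ties keep the lowest original acquisition
    index.  All b = 0 volumes are retained.
    """
    base = previous if previous is not None else scheme
    spec.validate_against(base)
    dw_idx = np.flatnonzero(base.dw_mask)
    u = base.directions[dw_idx]
    angle = np.degrees(np.arccos(np.clip(np.abs(u @ u.T), -1.0, 1.0)))
    shells = base.shells
    shell_of = base.shell_id[dw_idx]
    # positions into `dw_idx` per shell
    kept = {s: list(np.flatnonzero(shell_of == s)) for s in shells}
    dropped = {s: [] for s in shells}
    targets = {s: spec.per_shell_counts[s] for s in shells}

    def objective(kept_map) -> float:
        return _sc_objective(angle, [np.array(kept_map[s]) for s in shells])

    # greedy removal
    while any(len(kept[s]) > targets[s] for s in shells):
        best_val, best_shell, best_pos = -np.inf, None, None
        for s in shells:
            if len(kept[s]) <= targets[s]:
                continue
            for pos in range(len(kept[s])):
                trial = dict(kept)
                trial[s] = kept[s][:pos] + kept[s][pos + 1:]
                val = objective(trial)
                if val > best_val + 1e-12:
                    best_val, best_shell, best_pos = val, s, pos
        dropped[best_shell].append(kept[best_shell].pop(best_pos))

    # pairwise exchange refinement
    current = objective(kept)
    for _ in range(max_passes):
        improved = False
        for s in shells:
            for ki in range(len(kept[s])):
                for di in range(len(dropped[s])):
                    trial = dict(kept)
                    trial[s] = kept[s].copy()
                    trial[s][ki] = dropped[s][di]
                    val = objective(trial)
                    if val > current + 1e-12:
                        kept[s][ki], dropped[s][di] = dropped[s][di], kept[s][ki]
                        current = val
                        improved = True
        if not improved:
            break

    keep_vols = list(np.flatnonzero(~base.dw_mask))
    for s in shells:
        keep_vols.extend(dw_idx[sorted(kept[s])])
    return base.take(np.array(keep_vols))


def subsample_random(
    scheme: GradientScheme, spec: SubsetSpec, seed: int
) -> GradientScheme:
    """Random_TRUNC subset: seeded whole-scheme shuffle then truncation.

    The entire scheme — b = 0 volumes included — is shuffled with the
    seeded RNG and truncated to the same total volume count as the
    corresponding optimized subset (Σ per-shell counts + all b = 0
    volumes of the input).  Per-shell balance and the b = 0 count are
    therefore left to chance, exactly as when an acquisition whose order
    was never optimized is stopped early.  Deterministic given the seed.
    """
    spec.validate_against(scheme)
    rng = np.random.default_rng(seed)
    n_b0 = int((~scheme.dw_mask).sum())
    total = n_b0 + sum(spec.per_shell_counts.values())
    perm = rng.permutation(scheme.n_volumes)
    return scheme.take(perm[:total])
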