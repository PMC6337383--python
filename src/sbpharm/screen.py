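"""Pharmacophore screening of multi-conformer libraries.

Feature matching allows one omitted model feature (the n / n-1 hit rule),
prunes candidate correspondences by pairwise inter-feature distance
compatibility, aligns rigidly by Kabsch superposition, rejects conformers
whose heavy atoms penetrate exclusion spheres, and scores the surviving
matches with a fit score dominated by the matched feature count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import Molecule, PharmacophoreModel, group_conformers
from .dynophore import PerceptionRules, DEFAULT_RULES, perceive_ligand_features
from .errors import DegenerateGeometryError

DEFAULT_MAX_OMIT = 1


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation + translation minimizing RMSD of P onto Q.

    Returns (R, t, rmsd) with the aligned points given by P @ R.T + t.
    Reflections are forbidden (det(R) = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be equally sized (n, 3) arrays")
    if P.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a unique superposition")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if np.sum(S > 1e-10 * max(S[0], 1e-30)) < 2:
        raise DegenerateGeometryError("collinear or coincident point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    aligned = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
    return R, t, rmsd


def _align_or_fallback(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch, degrading to centroid translation for degenerate point sets."""
    try:
        return kabsch(P, Q)
    except DegenerateGeometryError:
        R = np.eye(3)
        t = Q.mean(axis=0) - P.mean(axis=0)
        aligned = P + t
        rmsd = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
        return R, t, rmsd


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    molecule_id: str
    conformer_id: str
    pairs: list[tuple[int, int]]  # (model feature idx, conformer feature idx)
    omitted: list[int]  # omitted model feature indices
    rotation: np.ndarray
    translation: np.ndarray
    feature_rmsd: float
    fit_score: float | None
    passed_exclusion: bool

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def check_exclusion(aligned_heavy: np.ndarray, model: PharmacophoreModel) -> bool:
    """False iff any aligned heavy atom lies strictly inside an exclusion sphere."""
    for ev in model.exclusion_volumes:
        d = np.linalg.norm(aligned_heavy - ev.center, axis=1)
        if np.any(d < ev.radius):
            return False
    return True


def fit_score(n_matched: int, feature_rmsd: float, mean_radius: float) -> float:
    """10 per matched feature + up to 9 for geometric tightness."""
    geometric = max(0.0, 1.0 - feature_rmsd / mean_radius) if mean_radius > 0 else 0.0
    return 10.0 * n_matched + 9.0 * geometric


def _compatible_assignments(
    model_subset: Sequence[int],
    model: PharmacophoreModel,
    conf_feats,
    conf_positions: np.ndarray,
    model_dists: np.ndarray,
):
    """Backtracking enumeration of kind-compatible, distance-consistent injections."""
    by_kind: dict[str, list[int]] = {}
    for ci, f in enumerate(conf_feats):
        by_kind.setdefault(f.kind, []).append(ci)
    assignment: list[int] = []
    used: set[int] = set()

    def backtrack(k: int):
        if k == len(model_subset):
            yield list(assignment)
            return
        mi = model_subset[k]
        for ci in by_kind.get(model.features[mi].kind, ()):
            if ci in used:
                continue
            ok = True
            for prev_k in range(k):
                mj = model_subset[prev_k]
                cj = assignment[prev_k]
                dm = model_dists[mi, mj]
                dc = np.linalg.norm(conf_positions[ci] - conf_positions[cj])
                tol = model.features[mi].radius + model.features[mj].radius
                if abs(dm - dc) > tol:
                    ok = False
                    break
            if ok:
                assignment.append(ci)
                used.add(ci)
                yield from backtrack(k + 1)
                assignment.pop()
                used.discard(ci)

    yield from backtrack(0)


def match_conformer(
    conformer: Molecule,
    model: PharmacophoreModel,
    max_omit: int = DEFAULT_MAX_OMIT,
    rules: PerceptionRules = DEFAULT_RULES,
    conformer_features=None,
) -> MatchResult | None:
    """Best match of one conformer against a model, or None.

    Correspondences of size >= n - max_omit are enumerated (kind-compatible,
    pairwise distances within the sum of the paired model tolerance radii),
    aligned by Kabsch on the matched positions, and accepted when every
    aligned conformer feature falls inside its model feature's sphere.  Among
    acceptances the highest fit score wins; ties prefer more matched features,
    then lower feature RMSD.
    """
    if conformer_features is None:
        conformer_features = perceive_ligand_features(conformer, rules)
    n = len(model.features)
    min_size = max(n - max_omit, 1)
    model_pos = model.positions()
    model_dists = np.linalg.norm(model_pos[:, None, :] - model_pos[None, :, :], axis=2)
    conf_positions = np.array([f.position for f in conformer_features]) if conformer_features else np.zeros((0, 3))
    heavy = conformer.heavy_coords()

    best: MatchResult | None = None
    best_key = None
    for size in range(n, min_size - 1, -1):
        for subset in combinations(range(n), size):
            for assignment in _compatible_assignments(subset, model, conformer_features, conf_positions, model_dists):
                P = conf_positions[assignment]
                Q = model_pos[list(subset)]
                R, t, rmsd = _align_or_fallback(P, Q)
                aligned = P @ R.T + t
                dev = np.linalg.norm(aligned - Q, axis=1)
                radii = np.array([model.features[mi].radius for mi in subset])
                if np.any(dev > radii):
                    continue
                aligned_heavy = heavy @ R.T + t
                passed = check_exclusion(aligned_heavy, model)
                score = fit_score(size, rmsd, float(radii.mean())) if passed else None
                result = MatchResult(
                    molecule_id=conformer.name,
                    conformer_id=conformer.properties.get("conformer_id", conformer.name),
                    pairs=list(zip(subset, assignment)),
                    omitted=[i for i in range(n) if i not in subset],
                    rotation=R,
                    translation=t,
                    feature_rmsd=rmsd,
                    fit_score=score,
                    passed_exclusion=passed,
                )
                # passed-exclusion results always beat failed ones; then
                # fit score, matched count, lower rmsd
                key = (passed, score if score is not None else -np.inf, size, -rmsd)
                if best_key is None or key > best_key:
                    best, best_key = result, key
    return best


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------


def screen_library(
    library: dict[str, list[Molecule]] | Sequence[Molecule],
    model: PharmacophoreModel,
    max_omit: int = DEFAULT_MAX_OMIT,
    rules: PerceptionRules = DEFAULT_RULES,
) -> list[MatchResult]:
    """Best hit per molecule over its conformers, fit-score descending.

    Only matches that satisfy the feature-count rule *and* the exclusion
    volumes count as hits.
    """
    if not isinstance(library, dict):
        library = group_conformers(list(library))
    if not library:
        raise ValueError("empty screening library")
    hits = []
    for mol_id, conformers in library.items():
        best = None
        best_key = None
        for conf in conformers:
            m = match_conformer(conf, model, max_omit=max_omit, rules=rules)
            if m is None or not m.passed_exclusion:
                continue
            key = (m.fit_score, m.n_matched, -m.feature_rmsd)
            if best_key is None or key > best_key:
                best, best_key = m, key
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda m: (-m.fit_score, m.molecule_id))
    return hits


def hits_to_frame(hits: Sequence[MatchResult]) -> pd.DataFrame:
    rows = [
        {
            "molecule_id": h.molecule_id,
            "conformer_id": h.conformer_id,
            "n_matched": h.n_matched,
            "omitted": len(h.omitted),
            "feature_rmsd": h.feature_rmsd,
            "fit_score": h.fit_score,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["molecule_id", "conformer_id", "n_matched", "omitted", "feature_rmsd", "fit_score"])


def cha_screen(
    library: dict[str, list[Molecule]] | Sequence[Molecule],
    models: Sequence[PharmacophoreModel],
    max_omit: int = DEFAULT_MAX_OMIT,
    rules: PerceptionRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Common hits approach: rank molecules by how many models retrieve them.

    Ties are broken by the mean fit score over the models that produced a hit.
    Molecules hitting no model are excluded.
    """
    if len(models) < 2:
        raise ValueError("cha_screen requires at least two models")
    if not isinstance(library, dict):
        library = group_conformers(list(library))
    counts: dict[str, int] = {}
    fits: dict[str, list[float]] = {}
    for model in models:
        for hit in screen_library(library, model, max_omit=max_omit, rules=rules):
            counts[hit.molecule_id] = counts.get(hit.molecule_id, 0) + 1
            fits.setdefault(hit.molecule_id, []).append(hit.fit_score)
    rows = [
        {"molecule_id": mid, "hit_count": c, "mean_fit": float(np.mean(fits[mid]))}
        for mid, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["molecule_id", "hit_count", "mean_fit"])
    return df.sort_values(["hit_count", "mean_fit", "molecule_id"], ascending=[False, False, True]).reset_index(drop=True)
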