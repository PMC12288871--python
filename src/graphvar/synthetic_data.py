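"""Desk-scale synthetic cohorts with a planted structural signal.

The generator emulates the shape of a folded-structure variant cohort:
idealized alpha-helical backbones (realistic 3.8 A consecutive CA spacing),
wild-type/variant structure pairs that differ by one residue identity plus a
local coordinate perturbation around the mutated site, genes grouped into
protein families, binary labels, and a continuous deleteriousness proxy on a
0-40 scale whose distribution shifts upward for the pathogenic class so that
the conventional binary cutoff (score >= 20) is meaningful.

The planted signal is purely geometric: pathogenic variants receive extra
coordinate noise near the mutation site on top of the baseline perturbation
applied to every variant, so structure-derived embeddings can separate the
classes while sequence identity alone cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AA_ALPHABET, Atom, ProteinStructure, Residue, write_pdb

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_structure",
    "generate_variant_pair",
    "generate_proxy_score",
    "generate_cohort",
    "write_cohort",
]

# ideal alpha-helix CA trace: rise per residue, turn per residue, helix radius
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
_HELIX_RADIUS = 2.3

# backbone/CB offsets from CA in the residue's local (rotated) frame
_ATOM_OFFSETS = {
    "N": np.array([-0.90, -1.00, -0.60]),
    "C": np.array([0.90, 1.00, 0.65]),
    "O": np.array([1.40, 1.50, 1.10]),
    "CB": np.array([1.30, -0.60, 0.40]),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

#: proxy-score centre for the benign class; pathogenic shifts upward
PROXY_CENTER = 15.0
PROXY_RANGE = (0.0, 40.0)

#: radius (A) around the mutated site's CA inside which atoms are perturbed
PERTURBATION_RADIUS = 10.0


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``effect_scale`` (A) is the extra coordinate perturbation applied to
    pathogenic variants on top of the baseline ``noise_sd`` (A) applied to
    every variant; ``proxy_effect`` is the upward mean shift of the proxy
    score for the pathogenic class, with spread ``proxy_noise_sd`` on the
    score scale.
    """

    n_genes: int = 50
    variants_per_gene: int = 10
    n_families: int = 20
    residues_per_protein: int = 30
    fraction_pathogenic: float = 0.5
    effect_scale: float = 2.0
    noise_sd: float = 0.3
    proxy_effect: float = 6.0
    proxy_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.variants_per_gene, self.n_families, self.residues_per_protein) < 1:
            raise ValueError("counts must be positive")
        if self.n_families > self.n_genes:
            raise ValueError("n_families must not exceed n_genes")
        if not 0.0 <= self.fraction_pathogenic <= 1.0:
            raise ValueError("fraction_pathogenic must be in [0, 1]")
        if min(self.effect_scale, self.noise_sd, self.proxy_effect, self.proxy_noise_sd) < 0:
            raise ValueError("scales must be non-negative")


@dataclass
class Cohort:
    variants: pd.DataFrame
    structures: dict = field(repr=False, default_factory=dict)
    config: CohortConfig | None = None

    @property
    def family_map(self) -> dict:
        return dict(zip(self.variants["protein_id"], self.variants["family_id"]))


def _rotation_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_structure(n_residues: int, seed: int = 0, structure_id: str = "synthetic") -> ProteinStructure:
    """Idealized alpha-helical backbone with a random 20-letter sequence.

    Atoms N, CA, C, O per residue plus CB for non-glycine; consecutive CA-CA
    distance is ~3.83 A by construction. Deterministic given the seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
    residues = []
    for i in range(n_residues):
        theta = np.deg2rad(_HELIX_TURN_DEG) * i
        ca = np.array(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
        )
        rot = _rotation_z(theta)
        atoms = [Atom("N", "N", ca + rot @ _ATOM_OFFSETS["N"]), Atom("CA", "C", ca)]
        atoms.append(Atom("C", "C", ca + rot @ _ATOM_OFFSETS["C"]))
        atoms.append(Atom("O", "O", ca + rot @ _ATOM_OFFSETS["O"]))
        if seq[i] != "G":
            atoms.append(Atom("CB", "C", ca + rot @ _ATOM_OFFSETS["CB"]))
        residues.append(Residue(position=i + 1, aa=seq[i], atoms=atoms))
    return ProteinStructure(id=structure_id, residues=residues, source="synthetic")


def generate_variant_pair(
    structure: ProteinStructure,
    position: int,
    alt_aa: str,
    perturb_scale: float = 0.0,
    seed: int = 0,
) -> tuple[ProteinStructure, ProteinStructure]:
    """(wild-type copy, variant) sharing one coordinate frame.

    The variant carries ``alt_aa`` at ``position`` and Gaussian noise of
    standard deviation ``perturb_scale`` on every atom whose distance to the
    site's CA is at most 10 A. No rotation or translation is applied, so
    coordinate differences reflect only the local perturbation.
    """
    if not 1 <= position <= structure.n_residues:
        raise ValueError(f"position {position} out of range 1..{structure.n_residues}")
    wt_res = structure.residues[position - 1]
    if alt_aa == wt_res.aa:
        raise ValueError(f"alt_aa {alt_aa!r} equals the wild-type residue at position {position}")
    if alt_aa not in AA_ALPHABET:
        raise ValueError(f"unknown amino acid {alt_aa!r}")

    wt = structure.copy()
    var = structure.copy()
    var_res = var.residues[position - 1]
    var_res.aa = alt_aa
    theta = np.deg2rad(_HELIX_TURN_DEG) * (position - 1)
    if alt_aa == "G":
        var_res.atoms = [a for a in var_res.atoms if a.name != "CB"]
    elif var_res.atom("CB") is None:
        var_res.atoms.append(
            Atom("CB", "C", var_res.ca.coords + _rotation_z(theta) @ _ATOM_OFFSETS["CB"])
        )

    if perturb_scale > 0:
        rng = np.random.default_rng(seed)
        site = var_res.ca.coords.copy()
        for res in var.residues:
            for atom in res.atoms:
                if np.linalg.norm(atom.coords - site) <= PERTURBATION_RADIUS:
                    atom.coords = atom.coords + rng.normal(0.0, perturb_scale, size=3)
    return wt, var


def generate_proxy_score(
    label: str, proxy_effect: float, noise_sd: float, seed: int = 0
) -> float:
    """CADD-like proxy: Normal(15, sd) for benign, Normal(15 + effect, sd)
    for pathogenic, clipped to [0, 40]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if label not in ("benign", "pathogenic"):
        raise ValueError(f"label must be benign/pathogenic, got {label!r}")
    rng = np.random.default_rng(seed)
    mean = PROXY_CENTER + (proxy_effect if label == "pathogenic" else 0.0)
    value = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return float(np.clip(value, *PROXY_RANGE))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate structures, variant pairs, labels and proxy scores.

    Genes are assigned round-robin to families; each gene has one wild-type
    protein and ``variants_per_gene`` variants at distinct sites. Pathogenic
    variants are perturbed with ``noise_sd + effect_scale``, benign with
    ``noise_sd``; the pathogenic count is ``round(fraction * n_variants)``.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_genes * config.variants_per_gene
    n_path = int(round(config.fraction_pathogenic * n_total))
    is_path = np.zeros(n_total, dtype=bool)
    is_path[rng.permutation(n_total)[:n_path]] = True

    rows = []
    structures = {}
    idx = 0
    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        family_id = f"F{g % config.n_families:03d}"
        protein_id = f"P{g:04d}"
        wt_structure = generate_structure(
            config.residues_per_protein, seed=int(rng.integers(2 ** 31)), structure_id=protein_id
        )
        structures[(protein_id, "wt")] = wt_structure
        seen = set()
        for _ in range(config.variants_per_gene):
            while True:
                position = int(rng.integers(1, config.residues_per_protein + 1))
                wt_aa = wt_structure.residues[position - 1].aa
                alt_aa = str(rng.choice([a for a in AA_ALPHABET if a != wt_aa]))
                key = f"{wt_aa}{position}{alt_aa}"
                if key not in seen:
                    seen.add(key)
                    break
            label = "pathogenic" if is_path[idx] else "benign"
            scale = config.noise_sd + (config.effect_scale if label == "pathogenic" else 0.0)
            _, var_structure = generate_variant_pair(
                wt_structure, position, alt_aa, perturb_scale=scale, seed=int(rng.integers(2 ** 31))
            )
            structures[(protein_id, f"var-{key}")] = var_structure
            proxy = generate_proxy_score(
                label, config.proxy_effect, config.proxy_noise_sd, seed=int(rng.integers(2 ** 31))
            )
            rows.append({
                "protein_id": protein_id,
                "gene_id": gene_id,
                "family_id": family_id,
                "position": position,
                "wt_aa": wt_aa,
                "alt_aa": alt_aa,
                "variant_key": key,
                "label": label,
                "proxy_score": proxy,
            })
            idx += 1
    return Cohort(variants=pd.DataFrame(rows), structures=structures, config=config)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Persist a cohort as a directory of PDB files plus variants.csv."""
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    for (protein_id, allele), structure in cohort.structures.items():
        write_pdb(structure, outdir / "structures" / f"{protein_id}_{allele}.pdb")
    cohort.variants.to_csv(outdir / "variants.csv", index=False)
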