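"""Charge-neutralization variants and simulate-and-classify scans.

Variants never move charge around: every bead either keeps its original
charge or is set to exactly zero.  The recognition-helix scan enumerates all
combinations of k retained charges out of the listed charged residues and
neutralizes everything else on the protein.  PCNA variants follow the three
published designs on a homotrimer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling_analysis import (
    ClassificationThresholds,
    CouplingResult,
    DEFAULT_THRESHOLDS,
    MechanismSummary,
    angular_trace,
    classify_mechanism,
    fit_theta_z,
)
from .simulator import SimulationConfig, run_simulation
from .structure_io import BDNADuplex, CGProtein

__all__ = [
    "ChargeVariant",
    "VariantScanResult",
    "enumerate_variants",
    "pcna_variant",
    "scan",
    "PCNA_SIX_POSITIVE_RESIDUES",
]

ResidueId = tuple[str, int]

#: The six positive charges retained in the "six positive residues" design.
PCNA_SIX_POSITIVE_RESIDUES: tuple[tuple[str, int], ...] = (
    ("LYS", 20), ("LYS", 77), ("LYS", 80),
    ("ARG", 149), ("HIS", 153), ("LYS", 217),
)


@dataclass(frozen=True)
class ChargeVariant:
    label: str
    retained: tuple[ResidueId, ...]
    neutralized: tuple[ResidueId, ...]
    charges: np.ndarray      # per-bead charge vector after application

    def apply(self, protein: CGProtein) -> CGProtein:
        return protein.with_charges(self.charges.copy(), label=self.label)


def _normalize_ids(protein: CGProtein, ids) -> list[tuple[str, int, int]]:
    """Resolve residue ids (chain, resnum) or bare resnum to bead indices."""
    out = []
    default_chain = str(protein.chain_ids[0])
    for rid in ids:
        if isinstance(rid, int):
            chain, num = default_chain, rid
        else:
            chain, num = str(rid[0]), int(rid[1])
        out.append((chain, num, protein.bead_index(chain, num)))
    return out


def _charged_residue_ids(protein: CGProtein, beads) -> tuple[ResidueId, ...]:
    return tuple(
        (str(protein.chain_ids[b]), int(protein.res_numbers[b])) for b in beads
    )


def enumerate_variants(
    protein: CGProtein,
    charged_ids,
    k_retained: int,
) -> list[ChargeVariant]:
    """All C(n, k) recognition-helix variants, lexicographically ordered.

    In each variant the retained residues keep their original charge and
    every other charged residue of the protein — inside or outside the helix
    — is neutralized.
    """
    resolved = _normalize_ids(protein, charged_ids)
    n = len(resolved)
    if not 0 <= k_retained <= n:
        raise ValueError(f"k_retained={k_retained} out of range for {n} residues")
    for chain, num, bead in resolved:
        if protein.charges[bead] == 0.0:
            raise ValueError(f"residue {chain}/{num} carries no charge to retain")

    originally_charged = np.where(protein.charges != 0.0)[0]
    variants: list[ChargeVariant] = []
    for combo in itertools.combinations(range(n), k_retained):
        charges = np.zeros_like(protein.charges)
        kept_beads = [resolved[i][2] for i in combo]
        for b in kept_beads:
            charges[b] = protein.charges[b]
        kept_set = set(kept_beads)
        neutral_beads = [b for b in originally_charged if b not in kept_set]
        label = "retain_" + "+".join(
            f"{resolved[i][0]}{resolved[i][1]}" for i in combo
        ) if combo else "retain_none"
        variants.append(ChargeVariant(
            label=f"k{k_retained}_{label}",
            retained=_charged_residue_ids(protein, kept_beads),
            neutralized=_charged_residue_ids(protein, neutral_beads),
            charges=charges,
        ))
    return variants


def pcna_variant(
    trimer: CGProtein,
    mode: str,
    keep_chain: str | None = None,
    six_positive_residues=PCNA_SIX_POSITIVE_RESIDUES,
) -> ChargeVariant:
    """One of the three published PCNA charge designs.

    ``charged_monomer`` keeps all charges on one chain; ``positive_monomer``
    keeps only that chain's positive charges; ``six_positive`` keeps exactly
    the six listed residues.  The input must be a homotrimer (3 chains).
    """
    chains = list(dict.fromkeys(trimer.chain_ids.tolist()))
    if len(chains) != 3:
        raise ValueError(f"PCNA variants need a 3-chain trimer, got {len(chains)} chains")
    keep = keep_chain or chains[0]
    if keep not in chains:
        raise ValueError(f"chain {keep!r} not present in trimer")

    on_keep = trimer.chain_ids == keep
    charges = np.zeros_like(trimer.charges)

    if mode == "charged_monomer":
        charges[on_keep] = trimer.charges[on_keep]
    elif mode == "positive_monomer":
        pos = on_keep & (trimer.charges > 0)
        charges[pos] = trimer.charges[pos]
    elif mode == "six_positive":
        missing = []
        for res_name, res_number in six_positive_residues:
            hit = np.where(
                on_keep & (trimer.res_numbers == res_number)
                & (trimer.res_names == res_name)
            )[0]
            if hit.size == 0:
                missing.append(f"{res_name}{res_number}")
                continue
            b = int(hit[0])
            if trimer.charges[b] <= 0:
                missing.append(f"{res_name}{res_number} (not positive)")
                continue
            charges[b] = trimer.charges[b]
        if missing:
            raise ValueError(
                f"residues absent or uncharged on chain {keep}: {', '.join(missing)}"
            )
    else:
        raise ValueError(
            "mode must be one of charged_monomer, positive_monomer, six_positive"
        )

    originally = np.where(trimer.charges != 0.0)[0]
    kept = np.where(charges != 0.0)[0]
    kept_set = set(kept.tolist())
    return ChargeVariant(
        label=f"pcna_{mode}",
        retained=_charged_residue_ids(trimer, kept),
        neutralized=_charged_residue_ids(
            trimer, [b for b in originally if b not in kept_set]
        ),
        charges=charges,
    )


# --------------------------------------------------------------------------
# Simulate-and-classify scans
# --------------------------------------------------------------------------

@dataclass
class VariantScanResult:
    table: pd.DataFrame
    fits: dict[tuple[str, float], list[CouplingResult]]
    summaries: dict[tuple[str, float], MechanismSummary]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _replicate_seed(master_seed: int, label: str, salt: float, replicate: int) -> int:
    # keyed by variant *label* so permuting the variant list only permutes rows
    tag = hashlib.sha256(f"{label}|{salt:.9f}".encode()).digest()
    key = int.from_bytes(tag[:8], "big")
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key, replicate))
    return int(ss.generate_state(1)[0])


def scan(
    protein: CGProtein,
    dna: BDNADuplex,
    variants: list[ChargeVariant],
    salts: list[float],
    config: SimulationConfig,
    replicates: int = 10,
    master_seed: int = 0,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    burn_in: float = 0.1,
) -> VariantScanResult:
    """Run replicate simulations per (variant, salt) cell and classify.

    Replicate seeds derive from the master seed plus the variant label and
    salt value, so results are reproducible and order-independent.  A failed
    simulation marks its replicate; a cell with no surviving replicate is
    marked failed and the scan continues.
    """
    if not variants or not salts:
        raise ValueError("need at least one variant and one salt concentration")
    rows = []
    fits: dict[tuple[str, float], list[CouplingResult]] = {}
    summaries: dict[tuple[str, float], MechanismSummary] = {}
    for variant in variants:
        mutated = variant.apply(protein)
        for salt in salts:
            cell_fits: list[CouplingResult] = []
            n_failed = 0
            for rep in range(replicates):
                seed = _replicate_seed(master_seed, variant.label, salt, rep)
                cfg = dataclasses.replace(config, salt_molar=salt, seed=seed)
                try:
                    traj = run_simulation(mutated, dna, cfg)
                    cell_fits.append(
                        fit_theta_z(angular_trace(traj), thresholds,
                                    burn_in=burn_in))
                except Exception:
                    n_failed += 1
            key = (variant.label, salt)
            fits[key] = cell_fits
            if cell_fits:
                summary = classify_mechanism(cell_fits, thresholds)
            else:
                summary = MechanismSummary(float("nan"), float("nan"), 0, "failed")
            summaries[key] = summary
            rows.append({
                "variant": variant.label,
                "salt_molar": salt,
                "mean_slope": summary.mean_slope,
                "stderr": summary.stderr,
                "classification": summary.classification,
                "n_replicates": summary.n_replicates,
                "n_failed": n_failed,
            })
    return VariantScanResult(pd.DataFrame(rows), fits, summaries)
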