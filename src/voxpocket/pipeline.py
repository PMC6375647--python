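"""End-to-end composition: PDB text -> canonically oriented voxel tensor."""

from __future__ import annotations

from dataclasses import dataclass

from . import pocketgrid, structures, voxelizer
from .potentials import EnergyGrid, PairPotential, energy_channels
from .structures import Ligand, ResidueSet, TypedStructure
from .voxelizer import CanonicalFrame, VoxelTensor


@dataclass
class PocketResult:
    """All intermediate products of one pocket's voxelization.

    Coordinates in ``grid`` and ``structure`` are expressed in the canonical
    frame so CAM results can be mapped back onto residues directly.
    """

    structure: TypedStructure          # canonical-frame protein
    ligand: Ligand
    binding: ResidueSet
    frame: CanonicalFrame
    grid: pocketgrid.PocketGrid        # canonical-frame refined grid
    energies: EnergyGrid               # canonical-frame energy grid
    tensor: VoxelTensor                # 14-channel energy tensor
    occupancy: VoxelTensor             # 2-channel shape tensor


def voxelize_complex(
    pdb_text: str,
    ligand_resname: str,
    pot: PairPotential,
    ligand_chain: str | None = None,
    binding_cutoff: float = 5.0,
    radius: float = 15.0,
    spacing: float = 1.0,
    exclusion_cutoff: float = 2.0,
    clip_mode: str = "hull",
    envelope_radius: float = 4.0,
    connectivity: int = 6,
    side: int = 32,
    typing_table=None,
) -> PocketResult:
    """Run parse -> type -> carve -> energies -> canonicalize -> voxelize."""
    parsed, hetero = structures.parse_structure(pdb_text)
    typed, _ = structures.assign_sybyl_types(parsed, typing_table)
    ligand = structures.select_ligand(hetero, ligand_resname, ligand_chain)
    binding = structures.binding_residues(typed, ligand, binding_cutoff)
    grid = pocketgrid.carve_pocket(
        typed, ligand, radius=radius, spacing=spacing,
        exclusion_cutoff=exclusion_cutoff, clip_mode=clip_mode,
        envelope_radius=envelope_radius, connectivity=connectivity)
    egrid = energy_channels(grid, typed, pot)
    frame = voxelizer.principal_axes(binding, ligand.center)
    canonical = voxelizer.canonicalize(egrid, frame)
    tensor = voxelizer.to_voxels(canonical, side=side, frame=frame)
    occupancy = voxelizer.to_occupancy(grid, frame, side=side)
    structure_canonical = typed.transformed(frame.rotation, frame.translation)
    return PocketResult(
        structure=structure_canonical,
        ligand=ligand,
        binding=binding,
        frame=frame,
        grid=canonical.grid,
        energies=canonical,
        tensor=tensor,
        occupancy=occupancy,
    )
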