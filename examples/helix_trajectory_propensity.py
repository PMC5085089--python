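"""Static vs dynamic contact maps on a synthetic helix trajectory.

Builds an ideal alpha-helix, verifies its i -> i-4 hydrogen-bond ladder in
the static map, then simulates one bond as a two-state telegraph process
and measures its time-averaged formation propensity and the windowed
propensity that exposes on what timescale the bond settles.
"""

from hbprop import (BondKey, dynamic_propensity, make_ideal_helix,
                    place_amide_hydrogens, realize_bond_frames,
                    static_contact_matrix, windowed_propensity)
from hbprop.synthetic import SyntheticBondSpec

helix = place_amide_hydrogens(make_ideal_helix(18))
static = static_contact_matrix(helix)
ladder = sorted(k.label for k, v in static.entries.items() if v == 1)
print(f"ideal 18-residue helix: {len(ladder)} bonds formed")
print("  ", ", ".join(ladder))

spec = SyntheticBondSpec(p_form=0.7, n_frames=4000, seed=1)
frames = realize_bond_frames(spec)
bond = BondKey.from_seq(5, 1)
pm = dynamic_propensity(frames, [bond])
print(f"\ntelegraph bond, stationary formation probability 0.7:")
print(f"  measured propensity over {pm.n_frames} frames: "
      f"{pm.entries[bond]:.4f}")

windows = windowed_propensity(frames, bond, n_windows=4)
print("  windowed propensity (4 blocks):",
      " ".join(f"{w:.3f}" for w in windows))
print("\nThe measured fraction sits near the prescribed 0.7; block-wise")
print("values fluctuate because the chain is autocorrelated, as real")
print("hydrogen-bond trajectories are.")
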