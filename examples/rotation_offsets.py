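"""Cue-card rotation: when does the map rotate, and when does it remap?

Three manipulations of a circular arena with a cue card at 0 degrees
(10 training sessions, cue bearing ~ wrapped normal sd 18 deg):

* 180 clean -- card rotated 180 deg, arena cleaned: the card is the only cue.
* 180 dirty -- card rotated 180 deg with the animal present: five extra
  low-fidelity cues (odor, path integration; sd 54 deg) stay put.
* 45 dirty  -- card rotated 45 deg, extra cues stay put.

For each, the model infers the reference-direction offset that best aligns
the probe with the trained state, then the same-vs-novel evidence ratio.
"""

from statemap.protocols import run_cue_rotation

table = run_cue_rotation(seed=17)
print(table.to_string(index=False))
print(
    "\nWith only the card (clean), the map follows it: offset near 180 deg."
    "\nWith anchoring cues (dirty), a 180 deg card rotation is usually"
    "\nignored (offset near 0; with the card and the extra cues nearly"
    "\nbalanced, some seeds instead follow the card) while a 45 deg"
    "\nrotation is partially followed (offset between 0 and 45).  Ratios"
    "\nstay positive -- the state is recognized, so place fields rotate"
    "\nrather than remap -- but the dirty 180 case sits much closer to 0"
    "\n(more uncertainty, hence more heterogeneous remapping)."
)
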