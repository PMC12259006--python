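"""Detect planted allosteric coupling between bundle state and linchpin pose.

Toy ensembles couple a latent open/closed helix-bundle variable to the
displacement of a linchpin residue.  The analysis never sees the latent
state: it classifies frames as primed/collapsed from the interface SASA
alone, then conditions the linchpin RMSD on that classification.  Three
planted scenarios mirror wild-type, a loss-of-function mutant (linchpin
pushed away in both states) and a constitutively primed mutant.
"""
from allostate import pipeline

runs = pipeline.run_allosteric_pipeline(seed=0, n_frames=2000)

print(f"primed/collapsed SASA cutoff (wild-type ensemble): {runs['WT'].cutoff:.0f} A^2")
print()
print(f"{'scenario':<12s} {'primed median':>14s} {'collapsed median':>17s}")
for name, run in runs.items():
    print(f"{name:<12s} {run.primed_median:>12.2f} A {run.collapsed_median:>15.2f} A")
print()
print(
    "Wild-type: the primed-conditional median linchpin RMSD is far below the\n"
    "collapsed-conditional one -- opening the bundle pre-organizes the\n"
    "linchpin (positive planted coupling).  The loss-of-function scenario\n"
    "right-shifts both conditional medians; the hyperactive scenario shows\n"
    "near-identical priming in both bundle states."
)
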