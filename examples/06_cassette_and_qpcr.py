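"""Emit cloning oligos for a guide and quantify activation by 2^-ddCt.

The insert for the single-transcript cassette is hammerhead ribozyme +
spacer (the HDV ribozyme and tracrRNA scaffold reside on the destination
plasmid); the hammerhead's first six bases are the reverse complement of
the spacer's first six. Activation is then read out from a qPCR Ct table
against dual references (actA, benA) with the Livak method.
"""

import nucleoguide as ng

spacer = "GATTACAGATTACAGATTAC"
insert = ng.emit_oligos(spacer, ng.OverhangSpec(forward="GTTAC", reverse="GTAAC"))
print(f"spacer        : {spacer}")
print(f"hammerhead    : {insert.hammerhead}")
print(f"forward oligo : {insert.forward_oligo}")
print(f"reverse oligo : {insert.reverse_oligo}")
print("The 5' GTTAC/GTAAC overhangs are placeholders for an Eco91I-type")
print("site — confirm them against your destination backbone.\n")

ct = ng.simulate_qpcr(true_fold=30.0, n_bio=3, ct_noise_sd=0.2, seed=5)
result = ng.fold_change(ct, "mdpE", ("actA", "benA"),
                        ["control_1", "control_2", "control_3"],
                        ["treated_1", "treated_2", "treated_3"])
print(f"per-replicate folds : {[round(f, 2) for f in result.folds]}")
print(f"mean fold change    : {result.mean_fold:.2f} (planted 30)")
print(f"t = {result.t_statistic:.2f}, p = {result.p_value:.3g} {result.stars}")
print("fold = 2^-(ddCt); stars: * p<0.05, ** p<0.01 (Student's t test).")
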