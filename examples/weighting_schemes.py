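"""Feature-type weights under the abundance-driven schemes.

A rare domain and an abundant low-complexity type are weighted under each
transform: weight is proportional to 1/(f(o)+1) where o is the type's
instance count in the reference proteome. The linear transform punishes
abundance hardest, the eighth root most gently; a minimum-weight floor can
keep a common but functionally decisive type (here a transmembrane
segment) influential.
"""

from archsim import FeatureCountTable, ScoringParams, compute_weights

counts = FeatureCountTable({"pfam:RARE": 3, "seg:lcr": 21000, "tmhmm:tm": 9000})
types = {"pfam:RARE", "seg:lcr", "tmhmm:tm"}

print(f"{'scheme':8s}  {'pfam:RARE':>10s}  {'seg:lcr':>10s}  {'tmhmm:tm':>10s}")
for scheme in ("uniform", "linear", "log10", "ln", "root4", "root8"):
    w = compute_weights(types, counts, ScoringParams(weighting=scheme))
    print(
        f"{scheme:8s}  {w['pfam:RARE']:10.4f}  {w['seg:lcr']:10.4f}  "
        f"{w['tmhmm:tm']:10.4f}"
    )

floored = compute_weights(
    types, counts, ScoringParams(weighting="ln", min_weights={"tmhmm:tm": 0.25})
)
print(
    f"\nln + floor   {floored['pfam:RARE']:10.4f}  {floored['seg:lcr']:10.4f}  "
    f"{floored['tmhmm:tm']:10.4f}   (tmhmm:tm floored at 0.25; sum still 1)"
)
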