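"""Map partner binding sites onto a substrate's tripartite degrons.

Builds a miniature p53-like substrate with a primary degron at residues
19-26, one partner binding the segment 10-40 (overlapping the degron), one
binding just downstream (adjacent within the 10-residue window) and one
binding far away, then runs the masking census.
"""

from degronon.masking import (
    BindingFeature,
    DegronAnnotation,
    DegronClass,
    FeatureKind,
    SequenceRegion,
    classify_region_relation,
    masking_census,
)

degron = DegronAnnotation(
    region=SequenceRegion("TP53", 19, 26),
    degron_class=DegronClass.PRIMARY,
    sequence="FSDLWKLL",
)

features = [
    BindingFeature("TP53", "CREBBP", SequenceRegion("TP53", 10, 40),
                   FeatureKind.SUFFICIENT_BINDING_REGION, 0.95, "I1"),
    BindingFeature("TP53", "PIN1", SequenceRegion("TP53", 30, 50),
                   FeatureKind.BINDING_ASSOCIATED_REGION, 0.80, "I2"),
    BindingFeature("TP53", "FARAWAY", SequenceRegion("TP53", 200, 250),
                   FeatureKind.SUFFICIENT_BINDING_REGION, 0.90, "I3"),
]

for f in features:
    rel, overlap, gap = classify_region_relation(degron.region, f.region)
    print(f"{f.partner_id:>8}: relation={rel.value:<9} overlap={overlap:>2}  gap={gap}")

rows, _, _ = masking_census(
    {"TP53": {f.partner_id for f in features}}, [degron], features
)
row = rows[0]
print(f"\npartners total: {row.n_partners_total}, "
      f"masking the primary degron: {row.n_masking[DegronClass.PRIMARY]}")
# CREBBP overlaps the degron and PIN1 sits within 10 residues of it, so both
# count as masking alternate partners; the distal binder does not.
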