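"""Predict viral protein locations by direct GO-term table lookup.

The packaged table maps each of six viral locations to one *essential*
cellular-component GO term plus its direct is_a/part_of *child* terms.
A query's GO-term set is matched against essential terms first; only if
none hits are child terms consulted.  All classes matched within the
winning tier are returned, which is why term sets touching several
classes over-predict — the limitation that motivates the SVM approach.
"""

from goloc import predict_lookup, virus_lookup_table

table = virus_lookup_table()
print("classes:", ", ".join(table.classes))

queries = {
    "essential hit": {"GO:0019028", "GO:0001234"},
    "two essential hits": {"GO:0030430", "GO:0042025"},
    "child-tier hit": {"GO:0019030"},
    "three child-tier hits": {"GO:0044155", "GO:0044166", "GO:0033655"},
    "no explicit terms": {"GO:0001234"},
}
for name, terms in queries.items():
    result = predict_lookup(terms, table)
    shown = "unpredictable" if result is None else \
        "; ".join(sorted(result, key=table.class_index))
    print(f"{name:22s} {sorted(terms)} -> {shown}")
print("\nEssential matches pre-empt child matches; a set matching neither "
      "tier is unpredictable.")
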