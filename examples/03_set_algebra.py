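"""Common/unique probe algebra and the specificity summary on toy sets.

Three "tumor types" share a core of hypermethylated probes; each also has a
private one.  The specificity table reports, per group, how many state
probes it has, how many are exclusive to it, and the percent exclusive.
"""

from methtopo.sets import StateSetCollection

import methtopo as mt

core = {"cg1", "cg2", "cg3", "cg4"}
collection = StateSetCollection(
    {
        "AML-like": {"hyper": frozenset(core | {"cgA"}), "hypo": frozenset()},
        "glioma-like": {"hyper": frozenset(core | {"cgB"}), "hypo": frozenset()},
        "carcinoma-like": {"hyper": frozenset(core), "hypo": frozenset()},
    }
)

print("common hyper:", sorted(mt.common_probes(collection, "hyper")))
for group in collection.groups:
    print(f"unique to {group}:", sorted(mt.unique_probes(collection, group, "hyper")))

print("\nVenn membership patterns:")
for pattern, count in mt.venn_counts(collection, "hyper").items():
    if count:
        print(f"  {' & '.join(pattern)}: {count}")

print("\nspecificity table:")
print(mt.specificity_table(collection).to_string(index=False))

# The four core probes are common to all groups; cgA/cgB are group-specific,
# giving the first two groups 20% tumor-specific hypermethylation.
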