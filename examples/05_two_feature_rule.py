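"""Interpret the two-feature separation with raw counts and thresholds.

The scatter table holds each sample's raw integer F*C and G*C counts;
an exhaustive search fits the accuracy-maximizing axis-aligned rule,
and per-class summaries show how often each class sits at zero — the
count-plane picture behind the classifier.
"""

from raacdip import (
    GeneratorConfig,
    class_summaries,
    default_scheme,
    fit_rule,
    generate,
    scatter_table,
)

dataset = generate(GeneratorConfig(seed=7))
table = scatter_table(dataset.records, default_scheme(), "F*C", "G*C")

rule, counts = fit_rule(table)
accuracy = (counts.TP + counts.TN) / counts.n
print(f"best threshold rule (training accuracy {accuracy:.3f}):")
print(" ", rule.describe())

print("\nper-class count summaries (x = F*C, y = G*C):")
print(class_summaries(table).to_string(index=False))
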