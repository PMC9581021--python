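"""Mine sentence-level interaction evidence for a protein pair.

Screens a tiny corpus: a sentence counts as evidence only when both
proteins are mentioned, an interaction term (bind, recruit, ...) survives
among its verb/noun tokens, and no context-exclusion entry fires. The
gene-expression sentence is co-mention but NOT interaction evidence -
the classic false-positive mode of interaction text mining.
"""

from ppistack import default_lexicons, evaluate_pair
from ppistack.textmine import DocumentText

documents = [
    DocumentText(
        doc_id="PM001",
        abstract="BRCA1 binds BARD1 to form an active ubiquitin ligase.",
        body_paragraphs=[
            "Coimmunoprecipitation confirmed that BRCA1 interacts with BARD1. "
            "BRCA1 also increases the expression of BARD1 in some tissues. "
            "Unrelated measurements are reported elsewhere."
        ],
    )
]
lexicons = default_lexicons({"P38398": ["BRCA1"], "Q99728": ["BARD1"]})

report = evaluate_pair(documents, ("P38398", "Q99728"), lexicons)
print(report.render_text())
print(
    "\nTwo sentences qualify as interaction evidence; the expression\n"
    "sentence co-mentions the proteins but is excluded by the context\n"
    "dictionary, so it is not counted as a hit."
)
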