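"""Built-in word lists.

The anxiety anchors are the affect keywords of the Zung Self-Rating Anxiety
Scale items (nervousness, fear, panic, somatic unease).  The stopword,
pronoun and clause-marker lists are small English lists sufficient for the
synthetic corpora this package analyses; real-platform deployments would
load platform/language-specific lists through :mod:`crowdanx.lexicon`.
"""

# Affect keywords drawn from the 20 SAS items.
ANXIETY_ANCHORS = (
    "nervous", "anxious", "afraid", "panic", "scared", "worried",
    "upset", "shaky", "restless", "dizzy", "faint", "terrified",
)

PERSONAL_PRONOUNS = (
    "i", "me", "my", "mine", "myself",
    "you", "your", "yours", "yourself",
    "he", "him", "his", "she", "her", "hers",
    "we", "us", "our", "ours", "ourselves",
    "they", "them", "their", "theirs",
)

# Subordinating/coordinating markers; a sentence containing none of these is
# counted as "simple" by the readability feature extractor.
CLAUSE_MARKERS = (
    "because", "although", "though", "while", "since", "unless",
    "whereas", "and", "but", "or", "which", "that", "if", "when",
)

STOPWORDS = frozenset(
    PERSONAL_PRONOUNS
    + CLAUSE_MARKERS
    + (
        "a", "an", "the", "is", "are", "was", "were", "be", "been", "being",
        "am", "do", "does", "did", "have", "has", "had", "will", "would",
        "can", "could", "shall", "should", "may", "might", "must",
        "to", "of", "in", "on", "at", "by", "for", "with", "from", "as",
        "into", "about", "over", "under", "up", "down", "out", "off",
        "too", "very", "much", "many", "more", "most", "some", "any",
        "no", "not", "so", "than", "then", "there", "here", "this",
        "these", "those", "it", "its", "what", "who", "how", "feel",
        "s", "t", "dont", "im", "get", "got", "go", "just",
    )
)
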