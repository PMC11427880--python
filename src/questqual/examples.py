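"""Worked-example question texts used throughout the documentation.

Q1 is an explicit question about the start of chronic kidney disease
care: interrogative words make up 7 of its 36 tokens, a clarity of
19.44%. Q2 shares plenty of background about the asker's condition but
never uses an interrogative word, so its clarity is 0 — the classic
high-context, low-clarity post.
"""

Q1 = (
    "What's the first thing doctors do when a child is diagnosed with "
    "chronic kidney disease? And what happens next. Like when you first "
    "go in what do they do? What do they tell you? what happens?"
)

Q2 = (
    "I have been early diagnosed with stage 3 kidney failure. Let me "
    "know thoughts on treatments? The condition stems from many years "
    "of high blood pressure. I am 55 and hope this doesn't lead to "
    "dialysis."
)
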