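compound_id,forced_final,rationale
161,TP,alpha1 antagonist: mammary effects across the class support a positive call despite the negative class decision
184,TN,"antifibrotic: unspecific tumor pattern, finally judged negative in the class narrative"
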