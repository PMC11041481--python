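# Question templates, one per line: singular form <TAB> plural form.
# {drugs} is replaced by the drug term(s); the first line is the canonical template.
Why was {drugs} prescribed to the patient?	Why were {drugs} prescribed to the patient?
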