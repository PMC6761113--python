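phrase,kind,direction,scope
no,negated,forward,6
not,negated,forward,6
without,negated,forward,6
no evidence of,negated,forward,6
no signs of,negated,forward,6
denies,negated,forward,6
denied,negated,forward,6
negative for,negated,forward,6
free of,negated,forward,6
absence of,negated,forward,6
ruled out,negated,backward,6
unremarkable for,negated,forward,6
if,hypothetical,forward,6
should,hypothetical,forward,6
could,hypothetical,forward,6
may,hypothetical,forward,6
might,hypothetical,forward,6
would,hypothetical,forward,6
consider,hypothetical,forward,6
concern for,hypothetical,forward,6
possible,hypothetical,forward,6
possibility of,hypothetical,forward,6
at risk for,hypothetical,forward,6
watch for,hypothetical,forward,6
return if,hypothetical,forward,6
history of,historical,forward,6
h/o,historical,forward,6
hx of,historical,forward,6
past history of,historical,forward,6
prior,historical,forward,6
previous,historical,forward,6
previously,historical,forward,6
status post,historical,forward,6
s/p,historical,forward,6
years ago,historical,backward,6
remote,historical,forward,6
but,terminator,forward,0
however,terminator,forward,0
;,terminator,forward,0
although,terminator,forward,0
except,terminator,forward,0
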