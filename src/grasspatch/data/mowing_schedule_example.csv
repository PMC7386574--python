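date,cut_height_cm
2002-07-11,10
2002-09-20,10
2003-06-20,10
2003-09-20,10
2004-06-20,10
2004-09-20,10
2005-06-20,10
2005-09-20,10
2006-06-20,10
2006-09-20,10
2007-06-20,10
2007-09-20,10
2008-06-20,10
2008-09-20,10
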