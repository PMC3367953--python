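the and for are but not you all can had her was one our out day get has him
his how man new now old see two way who did its let put say she too use
that with have this will your from they know want been good much some time
very when come here just like long make many more only over such take than
them well were what about into could there their which would other after
first also where these because through between during before under while
both each most any may might must shall upon among within without however
thus then being does against above below again further once same such few
more most own too very can will just should now
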