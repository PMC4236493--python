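a
an
and
are
as
at
be
but
by
for
had
has
have
if
in
into
is
it
no
not
of
on
or
such
that
the
their
then
there
these
they
this
to
was
will
with
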