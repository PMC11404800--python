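a
about
above
ache
aches
aching
across
activity
after
afternoon
again
ago
air
all
almost
also
always
am
an
and
ankle
ankles
any
anything
app
are
arm
arms
around
arthritis
as
asleep
asthma
at
attack
avoid
awake
away
back
bad
badly
balance
be
because
become
becomes
bed
been
before
being
below
bend
bending
better
between
big
bit
blood
body
both
bother
bothers
bothersome
breath
breathe
breathing
breathless
brief
burning
busy
but
by
calm
can
cannot
care
carry
chair
change
changed
changes
chest
chronic
climb
climbing
cold
come
comes
condition
constant
control
cook
cooking
cope
cough
coughing
could
cramp
cramps
daily
day
days
deep
diabetes
did
diet
difficult
difficulty
dinner
dizzy
do
doctor
does
doing
dose
down
drink
drinking
dry
during
dust
each
early
easier
easily
eat
eating
effort
end
energy
enough
even
evening
every
everything
exercise
exhausted
extra
failure
fall
falling
fast
fatigue
fatigued
feel
feeling
feels
feet
felt
few
fine
finger
fingers
first
flare
focus
foggy
following
food
foot
for
forget
from
full
garden
gardening
gentle
get
gets
getting
glucose
go
goes
going
good
got
grip
had
hand
hands
happen
happens
hard
harder
has
have
having
head
headache
heart
heavy
help
helped
helps
her
high
him
hip
hips
his
home
hot
hour
hours
house
how
hurt
hurts
i
if
in
inhaler
insulin
into
is
it
its
itself
joint
joints
just
keep
keeps
kitchen
knee
knees
know
last
late
lay
least
leg
legs
less
level
levels
lie
lift
lifting
light
like
limit
little
long
longer
low
lunch
lungs
make
makes
manage
managing
many
may
me
meal
meals
medication
medicine
mild
mind
minute
minutes
moment
more
morning
most
move
movement
moving
much
muscle
muscles
must
my
nap
nausea
near
need
needed
needs
never
night
no
normal
not
nothing
noticed
now
numb
of
off
often
on
once
one
only
or
other
out
outside
over
own
pace
pain
painful
pause
pills
plan
pollen
poor
prop
puffer
quick
quickly
quite
rain
rather
really
relax
relief
rest
rested
resting
rough
routine
sat
severe
sharp
she
short
shortness
shoulder
shoulders
shower
sick
since
sit
sitting
sleep
sleeping
sleepy
slept
slow
slowly
small
so
some
something
sometimes
son
soon
sore
soreness
sorenesses
stairs
stand
standing
start
started
stay
steady
steps
stiff
stiffness
still
stomach
stop
stopped
stress
stretch
stretching
strong
struggle
such
sudden
sugar
swelling
swollen
symptom
symptoms
take
taking
than
that
the
their
them
then
there
these
they
thing
things
think
this
tight
tightness
time
times
tired
tiredness
to
today
toe
toes
told
tonight
too
took
tried
trouble
try
trying
turn
twice
under
until
up
upset
us
use
used
usual
usually
very
wake
walk
walked
walking
want
warm
was
water
weak
weakness
weather
week
well
went
were
wheeze
wheezing
wheezy
when
while
whole
with
without
woke
work
worked
working
worse
worst
would
wrist
wrists
yard
yesterday
yet
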